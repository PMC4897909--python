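"""Per-chain annotation pipeline.

Runs the full descriptor stack over a parsed complex — charges, dot
surface, ASA/RSA/CX, electrostatic potentials and charged patches,
secondary structure, PSSM — and collects everything the encoder and the
propensity statistics need into one :class:`ChainAnnotation` per protein
chain.  Binding labels and per-residue contact counts are attached only
when the complex has RNA; every *feature* is computable without them, so
apo structures annotate identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import electrostatics as es
from . import structure as st
from . import surface as sf
from .physchem import physchem_feature
from .propensity import ChainStats

logger = logging.getLogger(__name__)


@dataclass
class AnnotationConfig:
    binding_cutoff: float = 5.0        # Å, heavy-atom RNA contact definition
    rsa_cutoff: float = 3.0            # %, surface-triplet membership
    probe: float = sf.DEFAULT_PROBE
    n_dots: int = sf.DEFAULT_DOTS
    eps: float = es.DBSCAN_EPS
    min_pts: int = es.DBSCAN_MIN_PTS
    potential_cutoff: float = es.POTENTIAL_CUTOFF
    cx_radius: float = sf.CX_SPHERE_RADIUS
    cx_mean_volume: float = sf.CX_MEAN_ATOM_VOLUME

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ChainAnnotation:
    """All per-residue descriptor blocks for one protein chain."""
    chain: st.Chain
    electro: np.ndarray            # (n, 3)  V_r, pos-patch, neg-patch
    rsa: np.ndarray                # (n, 5)  percent
    shape_class: np.ndarray        # (n,)
    ss3: np.ndarray                # (n,)
    pssm: np.ndarray               # (n, 20)
    pssm_fallback: bool
    physchem: np.ndarray           # (n, 10)
    ca_coords: np.ndarray          # (n, 3)
    breaks_after: np.ndarray       # (n-1,)
    labels: Optional[np.ndarray] = None     # bool (bound complexes only)
    contacts: Optional[np.ndarray] = None   # int
    triplet: Optional[np.ndarray] = None    # (n, 4), filled once a table exists
    config: AnnotationConfig = field(default_factory=AnnotationConfig)

    def __len__(self) -> int:
        return len(self.chain)

    @property
    def sequence(self) -> str:
        return self.chain.sequence

    def stats(self) -> ChainStats:
        """Propensity-statistics view; requires binding labels."""
        if self.labels is None or self.contacts is None:
            raise ValueError("chain has no binding labels (apo complex)")
        return ChainStats(
            sequence=self.sequence, rsa_all=self.rsa[:, 0], ss3=self.ss3,
            binding=self.labels, contacts=self.contacts,
            breaks_after=self.breaks_after,
        )

    def query_stats(self) -> ChainStats:
        """Label-free view used for prediction-time triplet lookups."""
        n = len(self)
        return ChainStats(
            sequence=self.sequence, rsa_all=self.rsa[:, 0], ss3=self.ss3,
            binding=np.zeros(n, bool), contacts=np.zeros(n, int),
            breaks_after=self.breaks_after,
        )


def annotate_complex(
    cx: st.Complex,
    config: AnnotationConfig | None = None,
    pssm_sources: Optional[dict[str, str]] = None,
    dssp_path: Optional[str] = None,
) -> list[ChainAnnotation]:
    """Annotate every protein chain of a complex.

    ``pssm_sources`` maps chain id to an ASCII PSSM path/text; chains
    without one fall back to the substitution-matrix profile (flagged).
    Without ``dssp_path`` the torsion-based 3-state assigner is used.
    """
    config = config or AnnotationConfig()
    if not cx.charges_assigned:
        st.assign_charges(cx)
    if dssp_path is not None:
        st.read_dssp(dssp_path, cx)
    else:
        needs = any(r.ss3 is None for r in cx.iter_protein_residues())
        if needs:
            st.assign_ss_fallback(cx)

    surface = sf.generate_surface(cx, probe=config.probe, n_dots=config.n_dots)
    sf.compute_asa(surface)
    rsa = sf.compute_rsa(surface)
    cx_records = sf.compute_cx(cx, sphere_radius=config.cx_radius,
                               mean_atom_volume=config.cx_mean_volume, surface=surface)

    label_set = None
    if cx.rna_chains:
        label_set = st.label_binding_residues(cx, cutoff=config.binding_cutoff)

    params = es.DbscanParams(eps=config.eps, min_pts=config.min_pts)
    annotations: list[ChainAnnotation] = []
    offset = 0
    for chain in cx.protein_chains:
        n = len(chain)
        state = es.chain_potentials(cx, surface, chain, params,
                                    cutoff=config.potential_cutoff)
        electro = np.array([es.electrostatic_feature(state, i) for i in range(n)])
        rsa_mat = np.array([rsa[offset + i].as_array() for i in range(n)])
        shape = np.array([cx_records[offset + i].shape_class for i in range(n)])
        ss3 = np.array([r.ss3 if r.ss3 is not None else 3 for r in chain.residues])
        if pssm_sources and chain.chain_id in pssm_sources:
            profile = st.read_pssm(pssm_sources[chain.chain_id], chain)
        else:
            profile = st.fallback_pssm(chain)
        phys = np.array([physchem_feature(r.aa_type) for r in chain.residues])
        annotations.append(ChainAnnotation(
            chain=chain, electro=electro, rsa=rsa_mat, shape_class=shape,
            ss3=ss3, pssm=profile.matrix, pssm_fallback=profile.fallback,
            physchem=phys, ca_coords=chain.ca_coords(),
            breaks_after=chain.breaks_after(),
            labels=None if label_set is None else label_set.labels[chain.chain_id],
            contacts=None if label_set is None else label_set.contacts[chain.chain_id],
            config=config,
        ))
        offset += n
    return annotations
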