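"""Dot surfaces, solvent accessibility and residue shape descriptors.

Generates a quasi-uniform accessible dot surface over the protein heavy
atoms (Shrake-Rupley style: candidate points on each atom's probe-expanded
sphere, retained when not inside any other atom's expanded sphere).  The
per-atom retained-point counts N_i feed the surface-weighted residue
points of the electrostatic descriptor; the retained fraction gives the
per-atom accessible surface area

    ASA_atom = (retained / candidate) * 4 pi (r + probe)^2 .

From per-atom ASA the module derives the five-category relative solvent
accessibility (all / main-chain / side-chain / non-polar side / polar
side, each normalized by the same category's area in an extended
Ala-X-Ala reference conformer computed with this very routine) and the
CX protrusion index with its four-way shape class (dented, intermediate,
protruded, buried).

Hydrogens are excluded from surface generation and ASA throughout; only
heavy atoms shape the surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Chain, Complex, Residue, StructureError

logger = logging.getLogger(__name__)

DEFAULT_PROBE = 1.4          # Å, water probe
DEFAULT_DOTS = 320           # candidate dots per atom
CX_SPHERE_RADIUS = 10.0      # Å
CX_MEAN_ATOM_VOLUME = 20.1   # Å^3
BURIED_ASA = 1.0             # Å^2; residues with no atom above this are "buried"

MAIN_CHAIN = {"N", "CA", "C", "O", "OXT"}
POLAR_ELEMENTS = {"N", "O", "S", "SE"}


@dataclass
class SurfaceModel:
    """Dot surface over the protein heavy atoms of one complex."""

    atoms: list[Atom]                       # flattened heavy atoms
    residue_of: np.ndarray                  # atom index -> residue index
    residues: list[Residue]
    counts: np.ndarray                      # retained dots per atom (N_i)
    n_candidates: int
    probe: float
    points: list[np.ndarray] = field(repr=False, default_factory=list)  # per atom (N_i, 3)
    asa: np.ndarray | None = None           # per-atom, filled by compute_asa

    def atom_indices_of_residue(self, res_idx: int) -> np.ndarray:
        return np.nonzero(self.residue_of == res_idx)[0]

    def residue_point_count(self, res_idx: int) -> int:
        """N: total surface points over all atoms of the residue."""
        return int(self.counts[self.atom_indices_of_residue(res_idx)].sum())


@dataclass
class RsaVector:
    rsa_all: float
    rsa_side: float
    rsa_main: float
    rsa_nonpolar_side: float
    rsa_polar_side: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rsa_all, self.rsa_side, self.rsa_main,
                         self.rsa_nonpolar_side, self.rsa_polar_side])


@dataclass
class CxRecord:
    residue_cx: float
    shape_class: int           # 0 dented, 1 intermediate, 2 protruded, 3 buried


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _flatten_heavy(cx_or_chain: Complex | Chain) -> tuple[list[Atom], np.ndarray, list[Residue]]:
    residues = (list(cx_or_chain.iter_protein_residues())
                if isinstance(cx_or_chain, Complex) else cx_or_chain.residues)
    atoms: list[Atom] = []
    owner: list[int] = []
    for ri, res in enumerate(residues):
        for a in res.atoms:
            if a.is_heavy:
                atoms.append(a)
                owner.append(ri)
    return atoms, np.array(owner, int), residues


def generate_surface(
    cx: Complex | Chain,
    probe: float = DEFAULT_PROBE,
    n_dots: int = DEFAULT_DOTS,
    keep_points: bool = True,
) -> SurfaceModel:
    """Accessible dot surface over all protein heavy atoms.

    A candidate dot on atom i's expanded sphere (radius r_i + probe) is
    retained iff it lies outside every other atom's expanded sphere.
    Buried atoms retain zero dots.
    """
    atoms, owner, residues = _flatten_heavy(cx)
    if not atoms:
        raise StructureError("no heavy atoms; cannot generate a surface")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([a.radius for a in atoms])
    dirs = fibonacci_sphere(n_dots)
    expanded = radii + probe
    tree = cKDTree(coords)
    reach = 2.0 * expanded.max()
    counts = np.zeros(len(atoms), int)
    points: list[np.ndarray] = []
    for i in range(len(atoms)):
        cand = coords[i] + expanded[i] * dirs
        neigh = [j for j in tree.query_ball_point(coords[i], r=reach) if j != i]
        if neigh:
            nb = np.asarray(neigh, int)
            d2 = ((cand[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            keep = ~np.any(d2 < (expanded[nb] ** 2)[None, :] - 1e-12, axis=1)
        else:
            keep = np.ones(n_dots, bool)
        counts[i] = int(keep.sum())
        if keep_points:
            points.append(cand[keep])
    return SurfaceModel(atoms=atoms, residue_of=owner, residues=residues,
                        counts=counts, n_candidates=n_dots, probe=probe,
                        points=points)


def compute_asa(surface: SurfaceModel) -> np.ndarray:
    """Per-atom ASA from retained-dot fractions; also stored on the atoms."""
    radii = np.array([a.radius for a in surface.atoms])
    area = 4.0 * math.pi * (radii + surface.probe) ** 2
    asa = area * surface.counts / surface.n_candidates
    surface.asa = asa
    for atom, a in zip(surface.atoms, asa):
        atom.asa = float(a)
    return asa


# -- reference areas --------------------------------------------------------

@lru_cache(maxsize=None)
def reference_areas(aa: str, probe: float = DEFAULT_PROBE,
                    n_dots: int = DEFAULT_DOTS) -> tuple[float, float, float, float, float]:
    """Category areas (all, side, main, nonpolar-side, polar-side) of residue
    type ``aa`` in an extended Ala-X-Ala conformer, computed with this
    module's own dot-surface ASA routine for self-consistency."""
    from .peptides import extended_tripeptide

    if aa not in "ACDEFGHIKLMNPQRSTVWY":
        aa = "A"   # generic reference for nonstandard types (logged by caller)
    chain = extended_tripeptide(aa)
    surf = generate_surface(chain, probe=probe, n_dots=n_dots, keep_points=False)
    compute_asa(surf)
    center = 1
    idx = surf.atom_indices_of_residue(center)
    cats = _category_areas([surf.atoms[i] for i in idx],
                           np.asarray(surf.asa)[idx])
    return cats


def _category_areas(atoms: list[Atom], asa: np.ndarray) -> tuple[float, float, float, float, float]:
    total = side = main = nonpolar = polar = 0.0
    for atom, a in zip(atoms, asa):
        total += a
        if atom.name in MAIN_CHAIN:
            main += a
        else:
            side += a
            if atom.element in POLAR_ELEMENTS:
                polar += a
            else:
                nonpolar += a
    return total, side, main, nonpolar, polar


def compute_rsa(surface: SurfaceModel, probe: float | None = None) -> list[RsaVector]:
    """Five-category RSA (percent) per residue.

    Categories with a zero reference area (e.g. glycine side-chain
    categories) are defined as 0 by convention.
    """
    if surface.asa is None:
        compute_asa(surface)
    probe = surface.probe if probe is None else probe
    out: list[RsaVector] = []
    for ri, res in enumerate(surface.residues):
        idx = surface.atom_indices_of_residue(ri)
        cats = _category_areas([surface.atoms[i] for i in idx],
                               np.asarray(surface.asa)[idx])
        if res.aa_type not in "ACDEFGHIKLMNPQRSTVWY":
            logger.debug("nonstandard residue %s: generic RSA reference", res.aa_type)
        refs = reference_areas(res.aa_type, probe, surface.n_candidates)
        vals = [100.0 * c / r if r > 1e-9 else 0.0 for c, r in zip(cats, refs)]
        out.append(RsaVector(*vals))
    return out


# -- CX protrusion index ----------------------------------------------------

def compute_cx(
    cx: Complex,
    sphere_radius: float = CX_SPHERE_RADIUS,
    mean_atom_volume: float = CX_MEAN_ATOM_VOLUME,
    surface: SurfaceModel | None = None,
) -> list[CxRecord]:
    """Per-residue CX shape descriptor.

    Per heavy atom, V_int = (heavy atoms within ``sphere_radius``, self
    included) x ``mean_atom_volume`` and V_ext = sphere volume - V_int;
    the raw ratio V_ext/V_int is mean-centered over the complex (the raw
    ratio is strictly positive, so centering is what makes the +/-0.5
    dented/protruded thresholds meaningful).  The residue CX sums the
    centered values of its atoms with ASA > 1 Å²; residues with no such
    atom are buried (class 3).
    """
    if surface is None:
        surface = generate_surface(cx)
    if surface.asa is None:
        compute_asa(surface)
    coords = np.array([a.coord for a in surface.atoms])
    tree = cKDTree(coords)
    n_inside = np.array([len(tree.query_ball_point(c, r=sphere_radius)) for c in coords])
    v_int = n_inside * mean_atom_volume
    v_sphere = 4.0 / 3.0 * math.pi * sphere_radius ** 3
    v_ext = np.maximum(v_sphere - v_int, 0.0)
    raw = v_ext / v_int
    centered = raw - raw.mean()
    asa = np.asarray(surface.asa)
    out: list[CxRecord] = []
    for ri in range(len(surface.residues)):
        idx = surface.atom_indices_of_residue(ri)
        exposed = idx[asa[idx] > BURIED_ASA]
        if exposed.size == 0:
            out.append(CxRecord(residue_cx=0.0, shape_class=3))
            continue
        total = float(centered[exposed].sum())
        if total < -0.5:
            cls = 0
        elif total > 0.5:
            cls = 2
        else:
            cls = 1
        out.append(CxRecord(residue_cx=total, shape_class=cls))
    return out


def export_residue_table(surface: SurfaceModel, rsa: list[RsaVector],
                         cx_records: list[CxRecord]) -> "object":
    """Per-residue ASA/RSA/CX table for inspection (pandas DataFrame)."""
    import pandas as pd

    if surface.asa is None:
        compute_asa(surface)
    asa = np.asarray(surface.asa)
    rows = []
    for ri, res in enumerate(surface.residues):
        idx = surface.atom_indices_of_residue(ri)
        rows.append({
            "chain": res.chain_id, "pdb_number": res.pdb_number, "aa": res.aa_type,
            "asa": float(asa[idx].sum()),
            "rsa_all": rsa[ri].rsa_all, "rsa_side": rsa[ri].rsa_side,
            "rsa_main": rsa[ri].rsa_main,
            "rsa_nonpolar_side": rsa[ri].rsa_nonpolar_side,
            "rsa_polar_side": rsa[ri].rsa_polar_side,
            "cx": cx_records[ri].residue_cx, "shape_class": cx_records[ri].shape_class,
        })
    return pd.DataFrame(rows)
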