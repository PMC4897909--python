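"""Idealized peptide construction.

Builds polypeptide backbones from ideal bond lengths/angles and supplied
(φ, ψ) torsions (NeRF internal-to-Cartesian placement), and attaches
pseudo side chains that carry the *real* heavy-atom names and elements of
each residue type on an idealized zig-zag geometry extending from Cβ.

These conformers serve two purposes: (i) the extended Ala-X-Ala reference
conformers from which per-residue-type reference accessible areas are
computed, and (ii) the deterministic synthetic complexes used throughout
the test fixtures.  Side-chain coordinates are pseudo-geometry — element
identity, connectivity depth and approximate reach are right; exact
rotamer chemistry is not.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .structure import AA_1TO3, Atom, Chain, ELEMENT_RADII, DEFAULT_RADIUS, Residue, _element_from_name

# ideal backbone internal coordinates (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
OMEGA = 180.0

#: canonical (φ, ψ) used for the named folds
FOLD_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}
#: extended state used for reference-area conformers
EXTENDED = (-139.0, 135.0)

#: heavy side-chain atom names beyond CB, in connectivity order
SIDECHAIN_ATOMS: dict[str, list[str]] = {
    "A": [],
    "R": ["CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "N": ["CG", "OD1", "ND2"],
    "D": ["CG", "OD1", "OD2"],
    "C": ["SG"],
    "Q": ["CG", "CD", "OE1", "NE2"],
    "E": ["CG", "CD", "OE1", "OE2"],
    "G": [],
    "H": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "I": ["CG1", "CG2", "CD1"],
    "L": ["CG", "CD1", "CD2"],
    "K": ["CG", "CD", "CE", "NZ"],
    "M": ["CG", "SD", "CE"],
    "F": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "P": ["CG", "CD"],
    "S": ["OG"],
    "T": ["OG1", "CG2"],
    "W": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "Y": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "V": ["CG1", "CG2"],
}

#: connectivity depth (bonds from CB) of each side-chain atom, used for reach
_DEPTHS: dict[str, dict[str, int]] = {
    "R": {"CG": 1, "CD": 2, "NE": 3, "CZ": 4, "NH1": 5, "NH2": 5},
    "N": {"CG": 1, "OD1": 2, "ND2": 2},
    "D": {"CG": 1, "OD1": 2, "OD2": 2},
    "C": {"SG": 1},
    "Q": {"CG": 1, "CD": 2, "OE1": 3, "NE2": 3},
    "E": {"CG": 1, "CD": 2, "OE1": 3, "OE2": 3},
    "H": {"CG": 1, "ND1": 2, "CD2": 2, "CE1": 3, "NE2": 3},
    "I": {"CG1": 1, "CG2": 1, "CD1": 2},
    "L": {"CG": 1, "CD1": 2, "CD2": 2},
    "K": {"CG": 1, "CD": 2, "CE": 3, "NZ": 4},
    "M": {"CG": 1, "SD": 2, "CE": 3},
    "F": {"CG": 1, "CD1": 2, "CD2": 2, "CE1": 3, "CE2": 3, "CZ": 4},
    "P": {"CG": 1, "CD": 2},
    "S": {"OG": 1},
    "T": {"OG1": 1, "CG2": 1},
    "W": {"CG": 1, "CD1": 2, "CD2": 2, "NE1": 3, "CE2": 3, "CE3": 3, "CZ2": 4, "CZ3": 4, "CH2": 5},
    "Y": {"CG": 1, "CD1": 2, "CD2": 2, "CE1": 3, "CE2": 3, "CZ": 4, "OH": 5},
    "V": {"CG1": 1, "CG2": 1},
}

#: Å per bond depth along the pseudo side chain.  Compact (helix-surface)
#: side chains drape at ~0.6 Å of radial gain per bond; fully extended ones
#: project at ~1.1 Å.  The fixture generator picks per fold.
SIDECHAIN_STEP = 1.10
SIDECHAIN_STEP_COMPACT = 0.60

#: residue types whose side chain reaches >= 3 bonds beyond CB — used by the
#: fixture generator for contact faces that must physically reach the RNA
LONG_SIDECHAIN_AAS = "RKEQMWFY"


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom D given A-B-C, |CD|, angle BCD and torsion ABCD."""
    angle = math.radians(angle_deg)
    torsion = -math.radians(torsion_deg)   # frame below is left-handed
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral Cβ from backbone N, Cα, C."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def _sidechain_coords(aa: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                      direction: Optional[np.ndarray] = None,
                      step: Optional[float] = None
                      ) -> list[tuple[str, np.ndarray]]:
    """Pseudo side chain: CB at the tetrahedral position, remaining atoms on a
    zig-zag extending outward at SIDECHAIN_STEP Å per bond depth.  ``direction``
    (default Cα→Cβ) lets callers point side chains away from the local
    backbone so they are surface-exposed rather than axis-leaning."""
    names = SIDECHAIN_ATOMS.get(aa)
    if names is None or aa == "G":
        return []
    cb = _cb_position(n, ca, c)
    out = [("CB", cb)]
    if not names:
        return out
    u = (cb - ca) if direction is None else np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    ref = np.cross(u, c - ca)
    nr = np.linalg.norm(ref)
    v = ref / nr if nr > 1e-8 else np.array([1.0, 0.0, 0.0])
    step = SIDECHAIN_STEP if step is None else step
    depths = _DEPTHS.get(aa, {})
    lateral_slot: dict[int, int] = {}
    for name in names:
        d = depths.get(name, 1)
        k = lateral_slot.get(d, 0)
        lateral_slot[d] = k + 1
        offset = 0.65 * ((-1) ** k) * math.ceil(k / 2 + 0.5) if k else 0.45 * ((-1) ** d)
        out.append((name, cb + step * d * u + offset * v))
    return out


def build_peptide(
    sequence: str,
    torsions: Sequence[tuple[float, float]],
    chain_id: str = "A",
    include_sidechains: bool = True,
    start_number: int = 1,
    sidechain_step: Optional[float] = None,
) -> Chain:
    """Build an idealized peptide chain with per-residue (φ, ψ).

    ``torsions[i]`` is (φ_i, ψ_i); φ of the first residue and ψ of the last
    are unused.  Returns a :class:`~rbres.structure.Chain` whose atoms carry
    element-default radii and zero charges.
    """
    nres = len(sequence)
    if len(torsions) != nres:
        raise ValueError("one (phi, psi) pair per residue required")
    # seed the first three backbone atoms
    bb: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, nres):
        prev = bb[-1]
        psi_prev = torsions[i - 1][1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi_prev)
        ca = place_atom(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, OMEGA)
        phi = torsions[i][0]
        c = place_atom(prev["C"], n, ca, B_CA_C, A_N_CA_C, phi)
        bb.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: trans to the next N (or to ψ=135 continuation at C-term)
    for i in range(nres):
        if i < nres - 1:
            o = place_atom(bb[i]["N"], bb[i]["CA"], bb[i]["C"], B_C_O, A_CA_C_O,
                           torsions[i][1] + 180.0)
        else:
            o = place_atom(bb[i]["N"], bb[i]["CA"], bb[i]["C"], B_C_O, A_CA_C_O, -45.0)
        bb[i]["O"] = o

    ca_all = np.array([bb[i]["CA"] for i in range(nres)])
    chain = Chain(chain_id=chain_id)
    for i, aa in enumerate(sequence):
        atoms = [Atom(name=nm, element=_element_from_name(nm), coord=bb[i][nm].copy(),
                      radius=ELEMENT_RADII.get(_element_from_name(nm), DEFAULT_RADIUS))
                 for nm in ("N", "CA", "C", "O")]
        if include_sidechains:
            # point side chains away from the local backbone centroid so that
            # they sit on the surface (radial on a helix, lateral on a strand)
            lo, hi = max(0, i - 3), min(nres, i + 4)
            local = ca_all[lo:hi].mean(axis=0)
            cb = _cb_position(bb[i]["N"], bb[i]["CA"], bb[i]["C"])
            direction = cb - local
            if np.linalg.norm(direction) < 1e-6:
                direction = cb - bb[i]["CA"]
            for nm, coord in _sidechain_coords(aa, bb[i]["N"], bb[i]["CA"],
                                               bb[i]["C"], direction,
                                               step=sidechain_step):
                el = _element_from_name(nm)
                atoms.append(Atom(name=nm, element=el, coord=coord,
                                  radius=ELEMENT_RADII.get(el, DEFAULT_RADIUS)))
        chain.residues.append(Residue(
            chain_id=chain_id, seq_index=i, pdb_number=str(start_number + i),
            aa_type=aa if aa in AA_1TO3 else "X", atoms=atoms,
        ))
    return chain


def extended_tripeptide(aa: str) -> Chain:
    """Extended Ala-X-Ala conformer used for reference accessible areas."""
    return build_peptide("A" + aa + "A", [EXTENDED] * 3, chain_id="_")


def sidechain_tip(residue: Residue) -> Optional[Atom]:
    """Most distal heavy side-chain atom (falls back to CA for Gly)."""
    best, best_d = None, -1.0
    ca = residue.ca
    if ca is None:
        return None
    for a in residue.heavy_atoms():
        if a.name in ("N", "CA", "C", "O", "OXT"):
            continue
        d = float(np.linalg.norm(a.coord - ca.coord))
        if d > best_d:
            best, best_d = a, d
    return best or ca
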