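"""Structural models and readers for protein-RNA complexes.

Parses PDB-format structures into a light internal model (atoms with
coordinates, partial charges and radii; residues; chains), labels
RNA-binding residues by a heavy-atom distance cutoff, and reads the
auxiliary per-chain inputs the feature pipeline consumes: PQR charge
files, DSSP secondary-structure output and ASCII PSSM profiles.

Conventions
-----------
* ``seq_index`` is the 0-based position along the parsed chain; author
  PDB numbering (with insertion code) is retained for reports only.
* A numbering gap > 1 in author numbering is treated as a chain break:
  no triplet window or sequential patch semantics rely on spanning it.
* First alternate-location conformer is kept; waters are stripped.
* "Heavy atom" excludes hydrogen and deuterium everywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# constants

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common variants mapped to their parent
    "MSE": "M", "SEC": "C", "HSD": "H", "HSE": "H",
}
AA_1TO3 = {v: k for k, v in list(AA_3TO1.items())[:20]}
STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"

#: residue names accepted as ribonucleotides (standard four + inosine and
#: frequently seen modified ribonucleotides); DNA (DA/DC/DG/DT) is excluded.
RNA_RESNAMES = {
    "A", "U", "G", "C", "I",
    "PSU", "1MA", "5MC", "7MG", "OMC", "OMG", "2MG", "M2G", "H2U",
    "5MU", "4SU", "UR3", "A2M", "MIA",
}
WATER_RESNAMES = {"HOH", "WAT", "DOD"}

#: fallback van der Waals radii by element (Å)
ELEMENT_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "SE": 1.90,
}
DEFAULT_RADIUS = 1.70

MAIN_CHAIN_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}

#: column order of the 20 score columns in an ASCII PSSM
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


# ---------------------------------------------------------------------------
# errors

class StructureError(ValueError):
    """Unparseable or contract-violating structural input."""


class MissingAlphaCarbonError(StructureError):
    """A selected protein residue lacks a Cα atom (chain rejected)."""


class AlignmentError(StructureError):
    """Auxiliary per-residue file does not align with the parsed chain."""


class FormatError(StructureError):
    """Malformed auxiliary file."""


# ---------------------------------------------------------------------------
# domain types

@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    charge: float = 0.0
    radius: float = DEFAULT_RADIUS
    asa: Optional[float] = None

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_index: int
    pdb_number: str
    aa_type: str
    atoms: list[Atom] = field(default_factory=list)
    is_rna_binding: Optional[bool] = None
    ss8: Optional[str] = None
    _ss3: Optional[int] = None

    def get_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.get_atom("CA")

    @property
    def ss3(self) -> Optional[int]:
        if self._ss3 is not None:
            return self._ss3
        if self.ss8 is not None:
            return map_ss8_to_ss3(self.ss8)
        return None

    @ss3.setter
    def ss3(self, value: int) -> None:
        self._ss3 = value

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms if a.is_heavy], float)

    @property
    def author_number(self) -> int:
        """Numeric part of the author residue number (insertion code dropped)."""
        digits = "".join(ch for ch in self.pdb_number if ch.isdigit() or ch == "-")
        return int(digits) if digits else self.seq_index


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa_type for r in self.residues)

    def breaks_after(self) -> np.ndarray:
        """Boolean array of length n-1; True where author numbering jumps by > 1."""
        nums = [r.author_number for r in self.residues]
        return np.array([nums[i + 1] - nums[i] > 1 for i in range(len(nums) - 1)], bool)

    def ca_coords(self) -> np.ndarray:
        out = []
        for r in self.residues:
            ca = r.ca
            out.append(ca.coord if ca is not None else r.heavy_coords().mean(axis=0))
        return np.array(out, float)


@dataclass
class Complex:
    protein_chains: list[Chain]
    rna_chains: list[Chain]
    source_id: str = ""
    charges_assigned: bool = False

    def iter_protein_residues(self) -> Iterable[Residue]:
        for ch in self.protein_chains:
            yield from ch.residues

    def protein_heavy_atoms(self) -> list[tuple[Residue, Atom]]:
        return [(r, a) for r in self.iter_protein_residues() for a in r.atoms if a.is_heavy]

    def all_protein_atoms(self) -> list[tuple[Residue, Atom]]:
        return [(r, a) for r in self.iter_protein_residues() for a in r.atoms]

    def rna_atom_coords(self) -> np.ndarray:
        coords = [a.coord for ch in self.rna_chains for r in ch.residues for a in r.atoms]
        return np.array(coords, float) if coords else np.zeros((0, 3))


@dataclass
class PssmProfile:
    matrix: np.ndarray          # (n_residues, 20) log-odds, PSSM_ALPHABET order
    fallback: bool = False      # True when derived from a substitution matrix

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class BindingLabelSet:
    cutoff: float
    labels: dict[str, np.ndarray]        # chain_id -> bool per residue
    contacts: dict[str, np.ndarray]      # chain_id -> RNA-contacting heavy atoms per residue


# ---------------------------------------------------------------------------
# small vector geometry (shared with the peptide builder)

def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return math.degrees(math.atan2(y, x))


def _element_from_name(name: str) -> str:
    """Infer element from a PDB atom name in a protein/nucleic-acid context."""
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        return "C"
    if stripped[0] in "HD" and name[:1].isdigit():
        return "H"
    first = stripped[0].upper()
    if first in ("C", "N", "O", "S", "P", "H"):
        return first
    if stripped[:2].upper() == "SE":
        return "SE"
    return first


# ---------------------------------------------------------------------------
# PDB reading

def _looks_like_rna(residue_names: Sequence[str]) -> bool:
    if not residue_names:
        return False
    hits = sum(1 for n in residue_names if n in RNA_RESNAMES)
    return hits / len(residue_names) > 0.5


def _looks_like_protein(residue_names: Sequence[str]) -> bool:
    if not residue_names:
        return False
    hits = sum(1 for n in residue_names if n in AA_3TO1)
    return hits / len(residue_names) > 0.5


def read_complex(
    pdb_source: str | Path,
    protein_chains: Optional[Sequence[str]] = None,
    rna_chains: Optional[Sequence[str]] = None,
) -> Complex:
    """Parse a PDB file (path or text) into a :class:`Complex`.

    ``protein_chains``/``rna_chains`` select chains by id; ``None`` means
    auto-detect (nucleotide chains by residue name, with O2' ribose
    presence as confirmation when available).  Pass ``rna_chains=[]`` for
    apo prediction mode.  Every selected protein residue must contain a
    Cα atom; violating chains are rejected with
    :class:`MissingAlphaCarbonError`.
    """
    import gemmi

    text: Optional[str] = None
    if isinstance(pdb_source, Path) or (
        isinstance(pdb_source, str) and "\n" not in pdb_source and Path(pdb_source).exists()
    ):
        source_id = Path(pdb_source).stem
        st = gemmi.read_structure(str(pdb_source))
    else:
        text = str(pdb_source)
        source_id = "inline"
        try:
            st = gemmi.read_pdb_string(text)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
            raise FormatError(f"unparseable PDB input: {exc}") from exc
    if len(st) == 0:
        raise FormatError("PDB input contains no model")
    st.remove_alternative_conformations()
    model = st[0]

    prot_out: list[Chain] = []
    rna_out: list[Chain] = []
    for gch in model:
        resnames = [res.name.strip() for res in gch if res.name.strip() not in WATER_RESNAMES]
        cid = gch.name
        is_rna = _looks_like_rna(resnames)
        is_prot = _looks_like_protein(resnames)
        want_prot = (protein_chains is None and is_prot) or (
            protein_chains is not None and cid in protein_chains
        )
        want_rna = (rna_chains is None and is_rna) or (
            rna_chains is not None and cid in rna_chains
        )
        if not (want_prot or want_rna):
            continue
        chain = Chain(chain_id=cid)
        for res in gch:
            rname = res.name.strip()
            if rname in WATER_RESNAMES:
                continue
            atoms: list[Atom] = []
            seen: set[str] = set()
            for at in res:
                if at.name in seen:       # residual altlocs
                    continue
                seen.add(at.name)
                el = at.element.name.upper() if at.element else ""
                if el in ("", "X"):
                    el = _element_from_name(at.name)
                atoms.append(Atom(
                    name=at.name,
                    element=el,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z], float),
                    radius=ELEMENT_RADII.get(el, DEFAULT_RADIUS),
                ))
            if not atoms:
                continue
            icode = res.seqid.icode.strip() if res.seqid.icode else ""
            residue = Residue(
                chain_id=cid,
                seq_index=len(chain.residues),
                pdb_number=f"{res.seqid.num}{icode}",
                aa_type=AA_3TO1.get(rname, rname if rname in RNA_RESNAMES else "X"),
                atoms=atoms,
            )
            if want_prot and not want_rna and rname not in AA_3TO1:
                if rname in RNA_RESNAMES:
                    pass  # mis-selected; fall through and skip below
                logger.debug("skipping hetero residue %s %s", rname, residue.pdb_number)
                continue
            chain.residues.append(residue)
        if not chain.residues:
            continue
        if want_prot and not is_rna:
            for r in chain.residues:
                if r.ca is None:
                    raise MissingAlphaCarbonError(
                        f"residue {r.aa_type} {cid}:{r.pdb_number} lacks a Calpha atom; "
                        f"chain {cid} rejected"
                    )
            prot_out.append(chain)
        elif want_rna:
            rna_out.append(chain)
    if protein_chains is not None:
        missing = set(protein_chains) - {c.chain_id for c in prot_out}
        if missing:
            raise StructureError(f"protein chain(s) not found: {sorted(missing)}")
    return Complex(protein_chains=prot_out, rna_chains=rna_out, source_id=source_id)


# ---------------------------------------------------------------------------
# charges: built-in PARSE-style table and PQR input

#: Simplified PARSE-style partial charges and radii for the 20 standard
#: residues.  Backbone amide/carbonyl values follow the PARSE force field
#: (N -0.40 / H +0.40 / C +0.55 / O -0.55); side-chain formal charges are
#: localized on the terminal heavy atoms of the charged groups.  Atoms not
#: listed are neutral with element-default radii.  PQR input (PDB2PQR with
#: the full PARSE set) remains the high-fidelity path.
_BACKBONE_CHARGES = {
    "N": (-0.40, 1.50), "H": (0.40, 1.00), "CA": (0.00, 2.00),
    "C": (0.55, 1.70), "O": (-0.55, 1.40), "OXT": (-0.55, 1.40),
}
_SIDECHAIN_CHARGES: dict[str, dict[str, tuple[float, float]]] = {
    "LYS": {"NZ": (1.00, 1.50)},
    "ARG": {"NH1": (0.50, 1.50), "NH2": (0.50, 1.50)},
    "ASP": {"OD1": (-0.50, 1.40), "OD2": (-0.50, 1.40)},
    "GLU": {"OE1": (-0.50, 1.40), "OE2": (-0.50, 1.40)},
    "HIS": {"ND1": (0.00, 1.50), "NE2": (0.00, 1.50)},
}


def builtin_charge(aa_type: str, atom_name: str) -> Optional[tuple[float, float]]:
    """(charge, radius) from the built-in table, or None when unlisted."""
    if atom_name in _BACKBONE_CHARGES:
        return _BACKBONE_CHARGES[atom_name]
    res3 = AA_1TO3.get(aa_type)
    if res3 and atom_name in _SIDECHAIN_CHARGES.get(res3, {}):
        return _SIDECHAIN_CHARGES[res3][atom_name]
    return None


def assign_charges(cx: Complex, pqr_source: Optional[str | Path] = None) -> Complex:
    """Assign per-atom charges/radii, from a PQR file or the built-in table.

    With the built-in table, atoms absent from it get charge 0 and the
    element-default radius (logged once per residue/atom-name pair).
    """
    if pqr_source is not None:
        _apply_pqr(cx, pqr_source)
        cx.charges_assigned = True
        return cx
    warned: set[tuple[str, str]] = set()
    for res in cx.iter_protein_residues():
        has_amide_h = res.get_atom("H") is not None
        for atom in res.atoms:
            entry = builtin_charge(res.aa_type, atom.name)
            if entry is not None:
                atom.charge, atom.radius = entry
                if atom.name == "N" and not has_amide_h:
                    # united-atom amide: fold the missing H (+0.40) into N so
                    # heavy-atom-only backbones stay net neutral
                    atom.charge += 0.40
            else:
                atom.charge = 0.0
                key = (res.aa_type, atom.name)
                if key not in warned and atom.is_heavy:
                    warned.add(key)
                    logger.debug("no built-in charge for %s %s; using 0", *key)
    cx.charges_assigned = True
    return cx


def _parse_pqr(text: str):
    records = []
    for line in text.splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        toks = line.split()
        if len(toks) < 10:
            raise FormatError(f"short PQR record: {line!r}")
        try:
            charge, radius = float(toks[-2]), float(toks[-1])
            x, y, z = (float(t) for t in toks[-5:-2])
        except ValueError as exc:
            raise FormatError(f"bad PQR record: {line!r}") from exc
        name, resname = toks[2], toks[3]
        # chain id column is optional in PQR
        if toks[4].isalpha() and len(toks[4]) <= 2 and not toks[4].lstrip("-").isdigit():
            chain_id, resnum = toks[4], toks[5]
        else:
            chain_id, resnum = "", toks[4]
        records.append((chain_id, resnum, resname, name, np.array([x, y, z]), charge, radius))
    return records


def _apply_pqr(cx: Complex, pqr_source: str | Path) -> None:
    text = Path(pqr_source).read_text() if (
        isinstance(pqr_source, Path)
        or ("\n" not in str(pqr_source) and Path(str(pqr_source)).exists())
    ) else str(pqr_source)
    records = _parse_pqr(text)
    index: dict[tuple[str, str], Residue] = {}
    for ch in cx.protein_chains:
        for r in ch.residues:
            index[(ch.chain_id, r.pdb_number)] = r
    mismatches = []
    for chain_id, resnum, resname, name, coord, charge, radius in records:
        res = index.get((chain_id, resnum)) if chain_id else None
        if res is None:  # try any chain
            hits = [r for (c, n), r in index.items() if n == resnum]
            res = hits[0] if len(hits) == 1 else None
        if res is None:
            mismatches.append(f"{chain_id}:{resnum} {resname} {name}")
            continue
        if AA_1TO3.get(res.aa_type, "") not in (resname, ""):
            mismatches.append(f"{chain_id}:{resnum} {resname} != {res.aa_type}")
            continue
        atom = res.get_atom(name)
        if atom is None:
            el = _element_from_name(name)
            if el in ("H", "D"):     # PQR adds hydrogens; keep them
                res.atoms.append(Atom(name=name, element=el, coord=coord,
                                      charge=charge, radius=radius))
            else:
                mismatches.append(f"{chain_id}:{resnum} {resname} missing atom {name}")
        else:
            atom.charge, atom.radius = charge, radius
    if mismatches:
        raise AlignmentError(
            "PQR/structure mismatch: " + "; ".join(mismatches[:10])
            + ("..." if len(mismatches) > 10 else "")
        )


# ---------------------------------------------------------------------------
# binding labels

def label_binding_residues(cx: Complex, cutoff: float = 5.0) -> BindingLabelSet:
    """Label each protein residue RNA-binding iff one of its heavy atoms is
    within ``cutoff`` Å of any RNA atom; also counts contacting heavy atoms
    per residue (used by the propensity statistics)."""
    from scipy.spatial import cKDTree

    rna = cx.rna_atom_coords()
    if rna.shape[0] == 0:
        raise StructureError(
            "complex has no RNA chains; binding labels undefined (use apo prediction mode)"
        )
    tree = cKDTree(rna)
    labels: dict[str, np.ndarray] = {}
    contacts: dict[str, np.ndarray] = {}
    for ch in cx.protein_chains:
        lab = np.zeros(len(ch), bool)
        cnt = np.zeros(len(ch), int)
        for i, res in enumerate(ch.residues):
            coords = res.heavy_coords()
            if coords.size == 0:
                continue
            d, _ = tree.query(coords, k=1)
            cnt[i] = int(np.sum(d <= cutoff))
            lab[i] = cnt[i] > 0
            res.is_rna_binding = bool(lab[i])
        labels[ch.chain_id] = lab
        contacts[ch.chain_id] = cnt
    return BindingLabelSet(cutoff=cutoff, labels=labels, contacts=contacts)


# ---------------------------------------------------------------------------
# secondary structure

def map_ss8_to_ss3(ss8: str) -> int:
    """8-state DSSP code to 3-state: {I,G,H}→1 helix, {E,B}→2 sheet, else 3 coil."""
    if ss8 in ("I", "G", "H"):
        return 1
    if ss8 in ("E", "B"):
        return 2
    if ss8 not in ("T", "S", " ", "-", "", "P"):
        logger.debug("unknown secondary-structure code %r mapped to coil", ss8)
    return 3


def read_dssp(dssp_path: str | Path, cx: Complex) -> None:
    """Attach 8-state DSSP assignments from an existing DSSP output file."""
    from Bio.PDB.DSSP import make_dssp_dict

    dssp_dict, _keys = make_dssp_dict(str(dssp_path))
    for ch in cx.protein_chains:
        missing = []
        for res in ch.residues:
            num = res.pdb_number
            icode = num[-1] if num and num[-1].isalpha() else " "
            resseq = int(num[:-1]) if icode != " " else int(num)
            entry = dssp_dict.get((ch.chain_id, (" ", resseq, icode)))
            if entry is None:
                missing.append(num)
                continue
            ss = entry[1]
            res.ss8 = " " if ss == "-" else ss
        if missing:
            raise AlignmentError(
                f"DSSP records missing for chain {ch.chain_id} residues {missing[:5]}"
            )


def assign_ss_fallback(cx: Complex) -> None:
    """Torsion-based 3-state assignment (helix/sheet/coil from φ/ψ).

    Used when no DSSP file is supplied.  Helix: φ ∈ (−120°, −30°) and
    ψ ∈ (−90°, −5°); sheet: φ ∈ (−180°, −90°] and ψ ∈ (90°, 180°] or
    ψ < −150°; otherwise coil.  Chain termini and break-adjacent residues
    (undefined φ or ψ) are coil.
    """
    for ch in cx.protein_chains:
        n = len(ch)
        breaks = ch.breaks_after()
        for i, res in enumerate(ch.residues):
            phi = psi = None
            if i > 0 and not (breaks[i - 1] if i - 1 < len(breaks) else False):
                prev = ch.residues[i - 1]
                if prev.get_atom("C") is not None and all(
                    res.get_atom(a) is not None for a in ("N", "CA", "C")
                ):
                    phi = dihedral_angle(prev.get_atom("C").coord, res.get_atom("N").coord,
                                         res.get_atom("CA").coord, res.get_atom("C").coord)
            if i < n - 1 and not (breaks[i] if i < len(breaks) else False):
                nxt = ch.residues[i + 1]
                if nxt.get_atom("N") is not None and all(
                    res.get_atom(a) is not None for a in ("N", "CA", "C")
                ):
                    psi = dihedral_angle(res.get_atom("N").coord, res.get_atom("CA").coord,
                                         res.get_atom("C").coord, nxt.get_atom("N").coord)
            if phi is None or psi is None:
                res.ss3 = 3
            elif -120 < phi < -30 and -90 < psi < -5:
                res.ss3 = 1
            elif -180 < phi <= -90 and (psi > 90 or psi < -150):
                res.ss3 = 2
            else:
                res.ss3 = 3


# ---------------------------------------------------------------------------
# PSSM profiles

def read_pssm(ascii_source: str | Path, chain: Chain) -> PssmProfile:
    """Read a standard ASCII PSSM and align it to the parsed chain.

    Rows whose residues are missing from the structure are dropped
    (structure sequence must be an in-order subsequence of the profile
    sequence); a surviving length mismatch raises :class:`AlignmentError`.
    """
    text = Path(ascii_source).read_text() if (
        isinstance(ascii_source, Path)
        or ("\n" not in str(ascii_source) and Path(str(ascii_source)).exists())
    ) else str(ascii_source)
    rows: list[tuple[str, np.ndarray]] = []
    for line in text.splitlines():
        toks = line.split()
        if len(toks) < 3 or not toks[0].lstrip("-").isdigit():
            continue
        if len(toks[1]) != 1 or not toks[1].isalpha():
            continue
        scores = toks[2:22]
        if len(scores) < 20:
            raise FormatError(f"PSSM row with {len(scores)} score columns: {line!r}")
        try:
            vec = np.array([float(s) for s in scores], float)
        except ValueError as exc:
            raise FormatError(f"non-numeric PSSM row: {line!r}") from exc
        rows.append((toks[1].upper(), vec))
    if not rows:
        raise FormatError("no PSSM rows found")
    seq = chain.sequence
    out = np.zeros((len(seq), 20))
    j = 0
    for i, aa in enumerate(seq):
        while j < len(rows) and rows[j][0] != aa and aa != "X":
            j += 1          # row for a residue missing from the structure
        if j >= len(rows):
            raise AlignmentError(
                f"chain sequence not alignable to PSSM (failed at residue {i} {aa})"
            )
        out[i] = rows[j][1]
        j += 1
    return PssmProfile(matrix=out, fallback=False)


def fallback_pssm(chain: Chain) -> PssmProfile:
    """Substitution-matrix profile: one BLOSUM62 row per residue type.

    Used when no precomputed PSSM is supplied; flagged in metadata.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(chain), 20))
    for i, res in enumerate(chain.residues):
        aa = res.aa_type if res.aa_type in STANDARD_AAS else None
        for j, col_aa in enumerate(PSSM_ALPHABET):
            out[i, j] = blosum[aa, col_aa] if aa else 0.0
    return PssmProfile(matrix=out, fallback=True)


# ---------------------------------------------------------------------------
# chain list files

def read_chain_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a plain-text chain list: one ``PDBID_CHAIN`` entry per line."""
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "_" not in line:
            raise FormatError(f"chain list entry {line!r} is not PDBID_CHAIN")
        pdb_id, chain_id = line.rsplit("_", 1)
        entries.append((pdb_id, chain_id))
    return entries
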