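"""Patch-expanded residue encoding.

Each residue carries five descriptor blocks — electrostatic (3), triplet
propensity (4), PSSM (20), geometry (6: five RSA categories + shape
class) and physicochemical (10).  Every block is expanded over its own
neighborhood patch: the target residue plus its s-1 nearest neighbors
either along the sequence (sequential patch) or by Cα-Cα distance
(structural patch), each block with its own patch type and size.  With
the default sizes (11, 7, 5, 5, 9) the concatenated vector has

    3*11 + 4*7 + 20*5 + 6*5 + 10*9 = 281

elements.  Patch slots that fall off a short chain are zero-padded so the
vector length is invariant.  Default patch types: structural for the
spatial descriptors (electrostatic, triplet, geometry), sequential for
the profile/identity descriptors (PSSM, physicochemical); both are
configurable per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .annotate import ChainAnnotation
from .propensity import PropensityTable, triplet_features

SEQUENTIAL = "sequential"
STRUCTURAL = "structural"


@dataclass(frozen=True)
class FeatureBlockSpec:
    name: str
    d: int                  # per-residue width
    patch_type: str
    s: int                  # patch size (>= 1)

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("patch size must be >= 1")
        if self.patch_type not in (SEQUENTIAL, STRUCTURAL):
            raise ValueError(f"unknown patch type {self.patch_type!r}")


def default_blocks() -> list[FeatureBlockSpec]:
    return [
        FeatureBlockSpec("electrostatic", 3, STRUCTURAL, 11),
        FeatureBlockSpec("triplet", 4, STRUCTURAL, 7),
        FeatureBlockSpec("pssm", 20, SEQUENTIAL, 5),
        FeatureBlockSpec("geometry", 6, STRUCTURAL, 5),
        FeatureBlockSpec("physchem", 10, SEQUENTIAL, 9),
    ]


@dataclass
class EncodingLayout:
    blocks: list[FeatureBlockSpec]
    offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.offsets:
            off, offsets = 0, []
            for b in self.blocks:
                offsets.append(off)
                off += b.d * b.s
            self.offsets = offsets

    @property
    def total_width(self) -> int:
        return sum(b.d * b.s for b in self.blocks)

    def columns_of(self, name: str) -> np.ndarray:
        for b, off in zip(self.blocks, self.offsets):
            if b.name == name:
                return np.arange(off, off + b.d * b.s)
        raise KeyError(name)

    def column_names(self) -> list[str]:
        names = []
        for b in self.blocks:
            for slot in range(b.s):
                for comp in range(b.d):
                    names.append(f"{b.name}.p{slot}.c{comp}")
        return names


def uniform_patch_size(blocks: Sequence[FeatureBlockSpec], s: int) -> list[FeatureBlockSpec]:
    """The same blocks with every patch size set to ``s`` (config helper)."""
    return [replace(b, s=s) for b in blocks]


def build_patch(
    center: int,
    n_residues: int,
    patch_type: str,
    s: int,
    ca_coords: Optional[np.ndarray] = None,
) -> list[Optional[int]]:
    """Ordered patch member indices for one residue; ``None`` marks padding.

    Sequential: the s residues minimizing |seq_index - center| (ties toward
    the N-terminus), emitted in ascending seq_index; a chain shorter than s
    is taken whole and zero-padded.  Structural: the center first, then its
    s-1 nearest residues by Cα-Cα distance in ascending distance (distance
    ties toward smaller seq_index).
    """
    if not 0 <= center < n_residues:
        raise IndexError("center outside chain")
    if patch_type == SEQUENTIAL:
        order = sorted(range(n_residues), key=lambda i: (abs(i - center), i))
        members = sorted(order[: min(s, n_residues)])
        return list(members) + [None] * (s - len(members))
    if ca_coords is None:
        raise ValueError("structural patch requires Calpha coordinates")
    d = np.linalg.norm(ca_coords - ca_coords[center], axis=1)
    order = sorted(range(n_residues), key=lambda i: (d[i], i))
    order.remove(center)
    members = [center] + order[: s - 1]
    return members[:s] + [None] * max(0, s - n_residues)


def block_matrices(ann: ChainAnnotation, table: Optional[PropensityTable]) -> dict[str, np.ndarray]:
    """Per-residue (n, d) matrix per block name."""
    n = len(ann)
    if ann.triplet is not None:
        trip = ann.triplet
    elif table is not None:
        trip = triplet_features(ann.query_stats(), table)
        ann.triplet = trip
    else:
        trip = np.zeros((n, 4))
    geometry = np.hstack([ann.rsa, ann.shape_class[:, None].astype(float)])
    return {
        "electrostatic": ann.electro,
        "triplet": trip,
        "pssm": ann.pssm,
        "geometry": geometry,
        "physchem": ann.physchem,
    }


def encode_chain(
    ann: ChainAnnotation,
    table: Optional[PropensityTable] = None,
    blocks: Optional[Sequence[FeatureBlockSpec]] = None,
) -> tuple[np.ndarray, EncodingLayout]:
    """Encode every residue of an annotated chain.

    Returns the (n, total_width) matrix (rows in seq_index order) and the
    layout describing block offsets.  Binding labels are never consulted.
    """
    blocks = list(blocks) if blocks is not None else default_blocks()
    layout = EncodingLayout(blocks=blocks)
    values = block_matrices(ann, table)
    n = len(ann)
    out = np.zeros((n, layout.total_width))
    patch_cache: dict[tuple[str, int], list[Optional[int]]] = {}
    for b, off in zip(blocks, layout.offsets):
        mat = values[b.name]
        if mat.shape[1] != b.d:
            raise ValueError(f"block {b.name}: width {mat.shape[1]} != spec {b.d}")
        for i in range(n):
            key = (b.patch_type, b.s)
            cache = patch_cache.setdefault(key, [None] * n)  # type: ignore[assignment]
            patch = cache[i]
            if patch is None:
                patch = build_patch(i, n, b.patch_type, b.s, ann.ca_coords)
                cache[i] = patch
            for slot, member in enumerate(patch):
                if member is not None:
                    out[i, off + slot * b.d: off + (slot + 1) * b.d] = mat[member]
    return out, layout


def encode_residue(
    ann: ChainAnnotation,
    index: int,
    table: Optional[PropensityTable] = None,
    blocks: Optional[Sequence[FeatureBlockSpec]] = None,
) -> np.ndarray:
    """Feature vector of a single residue (row of :func:`encode_chain`)."""
    matrix, _ = encode_chain(ann, table, blocks)
    return matrix[index]


def encode_dataset(
    annotations: Sequence[ChainAnnotation],
    table: Optional[PropensityTable] = None,
    blocks: Optional[Sequence[FeatureBlockSpec]] = None,
) -> tuple[np.ndarray, Optional[np.ndarray], EncodingLayout]:
    """Stack encodings over chains; labels are None when any chain is apo."""
    mats, labs = [], []
    layout = None
    for ann in annotations:
        m, layout = encode_chain(ann, table, blocks)
        mats.append(m)
        labs.append(ann.labels)
    X = np.vstack(mats)
    y = None
    if all(l is not None for l in labs):
        y = np.concatenate(labs).astype(bool)
    return X, y, layout
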