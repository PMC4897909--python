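"""Residue electrostatic surface potential and charged-patch clustering.

The potential at a surface point F is a bare Coulomb sum over the protein
atoms within a 7 Å shell, with a distance-dependent dielectric equal to
the distance itself, so each atom contributes q_i / |r_i - F|^2.  Per-atom
potentials V_a average the point potentials of the atom's surface dots;
per-residue potentials V_r average V_a over the residue's surfaced atoms;
residues without surface points have V_r = 0 by definition.

Each surfaced residue is then represented by a single 3-D point — the
surface-count-weighted centroid of its atom coordinates, sum_i x_i N_i/N —
and DBSCAN (eps = 7 Å, minPts = 3, neighbor count including the point
itself) clusters the positive-V_r and negative-V_r residues separately.
The largest cluster on each side is the largest positive (negative)
charged surface patch; the final descriptor per residue is

    (V_r, in largest positive patch, in largest negative patch)

with (0, 0, 0) for unsurfaced residues.  Clustering runs per chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import Chain, Complex
from .surface import SurfaceModel

logger = logging.getLogger(__name__)

POTENTIAL_CUTOFF = 7.0     # Å shell for the Coulomb sum
MIN_DISTANCE = 0.1         # Å floor avoiding the 1/d^2 singularity
DBSCAN_EPS = 7.0           # Å
DBSCAN_MIN_PTS = 3         # neighbors within eps, point itself included


@dataclass
class DbscanParams:
    eps: float = DBSCAN_EPS
    min_pts: int = DBSCAN_MIN_PTS

    def __post_init__(self) -> None:
        if self.eps <= 0 or self.min_pts < 1:
            raise ValueError("eps must be > 0 and min_pts >= 1")


@dataclass
class ChainPotentials:
    """Per-chain electrostatic state: residue potentials, representative
    points (None when unsurfaced) and largest-patch membership flags."""
    v_residue: np.ndarray                     # V_r, 0 for unsurfaced residues
    surfaced: np.ndarray                      # bool mask
    points: np.ndarray                        # (n, 3); NaN rows when unsurfaced
    in_largest_positive: np.ndarray
    in_largest_negative: np.ndarray

    def feature(self, i: int) -> np.ndarray:
        return np.array([
            self.v_residue[i],
            float(self.in_largest_positive[i]),
            float(self.in_largest_negative[i]),
        ])


def potential_at_points(
    points: np.ndarray,
    atom_coords: np.ndarray,
    charges: np.ndarray,
    cutoff: float = POTENTIAL_CUTOFF,
    min_distance: float = MIN_DISTANCE,
) -> np.ndarray:
    """V_F for an array of query points: sum of q_i/d^2 over atoms with
    d <= cutoff, distances floored at ``min_distance``."""
    points = np.atleast_2d(points)
    if atom_coords.shape[0] == 0:
        return np.zeros(len(points))
    tree = cKDTree(atom_coords)
    out = np.zeros(len(points))
    neigh = tree.query_ball_point(points, r=cutoff)
    for k, idx in enumerate(neigh):
        if not idx:
            continue
        idx = np.asarray(idx, int)
        d = np.linalg.norm(atom_coords[idx] - points[k], axis=1)
        d = np.maximum(d, min_distance)
        out[k] = float(np.sum(charges[idx] / d ** 2))
    return out


def potential_at_point(point, atoms, cutoff: float = POTENTIAL_CUTOFF) -> float:
    """Scalar convenience wrapper over :func:`potential_at_points`."""
    coords = np.array([a.coord for a in atoms])
    charges = np.array([a.charge for a in atoms])
    return float(potential_at_points(np.asarray(point, float)[None, :],
                                     coords, charges, cutoff)[0])


def residue_potentials(cx: Complex, surface: SurfaceModel,
                       cutoff: float = POTENTIAL_CUTOFF) -> tuple[np.ndarray, np.ndarray]:
    """(V_a per surface atom, V_r per residue).

    The Coulomb sum runs over *all* protein atoms of the complex with
    assigned charges, hydrogens included when present; RNA atoms never
    contribute (features must be computable for apo structures).
    """
    pairs = cx.all_protein_atoms()
    atom_coords = np.array([a.coord for _, a in pairs])
    charges = np.array([a.charge for _, a in pairs])
    v_atom = np.full(len(surface.atoms), np.nan)
    for i, pts in enumerate(surface.points):
        if len(pts) == 0:
            continue
        v_atom[i] = float(potential_at_points(pts, atom_coords, charges, cutoff).mean())
    v_res = np.zeros(len(surface.residues))
    for ri in range(len(surface.residues)):
        idx = surface.atom_indices_of_residue(ri)
        vals = v_atom[idx]
        vals = vals[~np.isnan(vals)]
        v_res[ri] = float(vals.mean()) if vals.size else 0.0
    return v_atom, v_res


def residue_points(surface: SurfaceModel) -> np.ndarray:
    """Representative point per residue: sum_i atom_i.coord * N_i / N over the
    residue's atoms (N_i = surface points on atom i).  NaN rows for residues
    with N = 0 (excluded from clustering)."""
    out = np.full((len(surface.residues), 3), np.nan)
    for ri in range(len(surface.residues)):
        idx = surface.atom_indices_of_residue(ri)
        n_i = surface.counts[idx].astype(float)
        n_total = n_i.sum()
        if n_total == 0:
            continue
        coords = np.array([surface.atoms[i].coord for i in idx])
        out[ri] = (coords * (n_i / n_total)[:, None]).sum(axis=0)
    return out


def residue_point(surface: SurfaceModel, res_idx: int) -> np.ndarray:
    """Representative point of one residue; raises for unsurfaced residues."""
    pt = residue_points(surface)[res_idx]
    if np.any(np.isnan(pt)):
        raise ValueError(f"residue index {res_idx} has no surface points")
    return pt


def cluster_points(points: np.ndarray, params: DbscanParams | None = None) -> np.ndarray:
    """Density-based clustering of 3-D points; -1 labels noise.

    Core point: >= min_pts neighbors within eps, the point itself
    included.  Points are processed in input order, which (with callers
    feeding residues in ascending seq_index) fixes border-point
    assignment deterministically.
    """
    from sklearn.cluster import DBSCAN

    params = params or DbscanParams()
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) == 0:
        return np.zeros(0, int)
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(points)
    return labels.astype(int)


def _largest_cluster(labels: np.ndarray, seq_indices: np.ndarray) -> int | None:
    """Label of the largest cluster; ties broken by smallest min seq_index."""
    ids = [l for l in np.unique(labels) if l >= 0]
    if not ids:
        return None
    best, best_key = None, None
    for l in ids:
        members = seq_indices[labels == l]
        key = (-len(members), int(members.min()))
        if best_key is None or key < best_key:
            best, best_key = int(l), key
    n_top = sum(1 for l in ids if (labels == l).sum() == (labels == best).sum())
    if n_top > 1:
        logger.info("largest-patch tie among %d clusters; smallest seq_index wins", n_top)
    return best


def largest_patches(
    v_res: np.ndarray,
    points: np.ndarray,
    surfaced: np.ndarray,
    params: DbscanParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Flags (in_largest_positive, in_largest_negative) per residue.

    Residues with V_r > 0 (resp. < 0) among the surfaced ones are
    clustered independently; the max-cardinality cluster on each side is
    the largest patch.  Unsurfaced residues carry zero flags.
    """
    params = params or DbscanParams()
    n = len(v_res)
    pos_flag = np.zeros(n, bool)
    neg_flag = np.zeros(n, bool)
    for sign, flags in ((1, pos_flag), (-1, neg_flag)):
        mask = surfaced & (sign * v_res > 0)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        labels = cluster_points(points[idx], params)
        top = _largest_cluster(labels, idx)
        if top is None:
            continue
        flags[idx[labels == top]] = True
    return pos_flag, neg_flag


def chain_potentials(
    cx: Complex,
    surface: SurfaceModel,
    chain: Chain,
    params: DbscanParams | None = None,
    cutoff: float = POTENTIAL_CUTOFF,
) -> ChainPotentials:
    """Full electrostatic descriptor state for one protein chain."""
    _, v_res_all = residue_potentials(cx, surface, cutoff)
    pts_all = residue_points(surface)
    # map the chain's residues into the flattened complex residue list
    offsets = [i for i, r in enumerate(surface.residues) if r.chain_id == chain.chain_id]
    sel = np.array(offsets, int)
    v_res = v_res_all[sel]
    pts = pts_all[sel]
    surfaced = ~np.isnan(pts).any(axis=1)
    pos, neg = largest_patches(v_res, pts, surfaced, params)
    return ChainPotentials(v_residue=v_res, surfaced=surfaced, points=pts,
                           in_largest_positive=pos, in_largest_negative=neg)


def electrostatic_feature(state: ChainPotentials, i: int) -> np.ndarray:
    """3-vector (V_r, positive-patch flag, negative-patch flag); all zero for
    residues without surface points."""
    if not state.surfaced[i]:
        return np.zeros(3)
    return state.feature(i)
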