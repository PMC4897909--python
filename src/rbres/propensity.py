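"""Triplet interface propensity statistics.

A *surface triplet* is three consecutive residues (no chain break) whose
all-atom RSA each exceeds a cutoff (default 3 %).  An *interface triplet*
is a surface triplet whose center residue binds RNA; it falls in one of
four subtypes by the binding status of its flanks:

    subtype 1: both flanks bind       subtype 2: first flank only
    subtype 3: third flank only       subtype 4: neither flank

For each ordered triplet type x and subtype k, the propensity pools
per-chain log-ratio terms

    R_xk = sum_p f_{x,p,k} * ln(f_{x,p,k} / f_{x',p})

where f_{x,p,k} = N_{x,k}/N_all is the fraction of chain p's
RNA-contacting heavy atoms that sit inside subtype-k interface instances
of x (contacts counted over all three residues of each instance), and
f_{x',p} = T_x/T_all is x's frequency among all surface triplets of the
chain.  Chains where x is absent contribute 0 (the f ln f limit).

A secondary-structure propensity conditions on the 3-state class s of the
center residue:

    I_{x,s} = (interface instances of x with state s, pooled over chains)
              / (surface instances of x, any state, pooled over chains)

so I_{x,s} in [0,1] and sum_s I_{x,s} <= 1.  The per-residue descriptor is
the 4-vector (I_{x,s} R_x1, ..., I_{x,s} R_x4), zero when the residue's
window is not a surface triplet, sits at a terminus/break, or is unseen
in the table.  Prediction-time lookups use only the query's RSA and
secondary structure — never its binding labels.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

DEFAULT_RSA_CUTOFF = 3.0   # percent


@dataclass
class ChainStats:
    """Per-chain summary consumed by the propensity statistics."""
    sequence: str
    rsa_all: np.ndarray          # percent, per residue
    ss3: np.ndarray              # 1 helix / 2 sheet / 3 coil
    binding: np.ndarray          # bool per residue
    contacts: np.ndarray         # RNA-contacting heavy atoms per residue
    breaks_after: np.ndarray     # bool, length n-1

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in ("rsa_all", "ss3", "binding", "contacts"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != sequence length")
        if len(self.breaks_after) != max(n - 1, 0):
            raise ValueError("breaks_after must have length n-1")


@dataclass
class PropensityTable:
    R: dict[str, np.ndarray]                 # triplet -> (R_x1..R_x4)
    I: dict[str, np.ndarray]                 # triplet -> (I_x1, I_x2, I_x3)
    rsa_cutoff: float = DEFAULT_RSA_CUTOFF
    n_chains: int = 0
    provenance: dict = field(default_factory=dict)

    def lookup(self, triplet: str, ss3: int) -> np.ndarray:
        """I_{x,s} * (R_x1..R_x4); zeros for unseen triplets."""
        r = self.R.get(triplet)
        if r is None:
            return np.zeros(4)
        i_val = self.I.get(triplet, np.zeros(3))[ss3 - 1]
        return i_val * r

    def summed_R(self, triplet: str) -> float:
        r = self.R.get(triplet)
        return float(r.sum()) if r is not None else 0.0


def surface_triplets(stats: ChainStats, rsa_cutoff: float = DEFAULT_RSA_CUTOFF
                     ) -> list[tuple[int, str]]:
    """All (center index, triplet type) windows i-1,i,i+1 with no chain break
    and all three residues above the RSA cutoff."""
    n = len(stats.sequence)
    out = []
    for i in range(1, n - 1):
        if stats.breaks_after[i - 1] or stats.breaks_after[i]:
            continue
        if (stats.rsa_all[i - 1] > rsa_cutoff and stats.rsa_all[i] > rsa_cutoff
                and stats.rsa_all[i + 1] > rsa_cutoff):
            out.append((i, stats.sequence[i - 1:i + 2]))
    return out


def classify_subtype(first_binds: bool, third_binds: bool, center_binds: bool = True) -> int:
    """Subtype id from flank binding labels; the center must bind."""
    if not center_binds:
        raise ValueError("interface triplet requires an RNA-binding center residue")
    if first_binds and third_binds:
        return 1
    if first_binds:
        return 2
    if third_binds:
        return 3
    return 4


def build_table_from_stats(
    chains: Sequence[ChainStats],
    rsa_cutoff: float = DEFAULT_RSA_CUTOFF,
    provenance: Optional[dict] = None,
) -> PropensityTable:
    """Pool the propensity statistics over a training set of chains."""
    if not chains:
        raise ValueError("empty training set")
    r_acc: dict[str, np.ndarray] = {}
    i_num: dict[str, np.ndarray] = {}    # interface count by center ss state
    i_den: dict[str, int] = {}           # surface count, any state
    n_used = 0
    for stats in chains:
        trips = surface_triplets(stats, rsa_cutoff)
        t_all = len(trips)
        if t_all == 0:
            continue
        n_used += 1
        n_all = int(stats.contacts.sum())
        t_x: dict[str, int] = {}
        for _, trip in trips:
            t_x[trip] = t_x.get(trip, 0) + 1
        for _, trip in trips:
            i_den[trip] = i_den.get(trip, 0) + 1
        n_xk: dict[str, np.ndarray] = {}
        for center, trip in trips:
            if not stats.binding[center]:
                continue
            sub = classify_subtype(bool(stats.binding[center - 1]),
                                   bool(stats.binding[center + 1]))
            inst_contacts = int(stats.contacts[center - 1:center + 2].sum())
            n_xk.setdefault(trip, np.zeros(4))[sub - 1] += inst_contacts
            s = int(stats.ss3[center])
            i_num.setdefault(trip, np.zeros(3))[s - 1] += 1
        if n_all == 0:
            continue
        for trip, counts in n_xk.items():
            f_surface = t_x[trip] / t_all
            f = counts / n_all
            term = np.zeros(4)
            nz = f > 0
            term[nz] = f[nz] * np.log(f[nz] / f_surface)
            r_acc[trip] = r_acc.get(trip, np.zeros(4)) + term
    if n_used == 0:
        raise ValueError("no chain contributed surface triplets")
    i_table = {trip: i_num[trip] / i_den[trip] for trip in i_num}
    return PropensityTable(R=r_acc, I=i_table, rsa_cutoff=rsa_cutoff,
                           n_chains=n_used, provenance=provenance or {})


def triplet_features(
    stats: ChainStats,
    table: PropensityTable,
    rsa_cutoff: Optional[float] = None,
) -> np.ndarray:
    """(n, 4) triplet descriptor matrix for a query chain.

    Uses only RSA, secondary structure and the trained table — binding
    labels on the query (if any) are never read.
    """
    cutoff = table.rsa_cutoff if rsa_cutoff is None else rsa_cutoff
    n = len(stats.sequence)
    out = np.zeros((n, 4))
    for center, trip in surface_triplets(stats, cutoff):
        out[center] = table.lookup(trip, int(stats.ss3[center]))
    return out


def triplet_feature(stats: ChainStats, center: int, table: PropensityTable) -> np.ndarray:
    """4-vector for one residue (zeros at termini/breaks/buried/unseen)."""
    return triplet_features(stats, table)[center]


# ---------------------------------------------------------------------------
# serialization

def save_table(table: PropensityTable, path: str | Path) -> None:
    payload = {
        "format": "rbres-propensity-v1",
        "rsa_cutoff": table.rsa_cutoff,
        "n_chains": table.n_chains,
        "provenance": table.provenance,
        "triplets": {
            trip: {
                "R": [float(v) for v in table.R[trip]],
                "I": [float(v) for v in table.I.get(trip, np.zeros(3))],
            }
            for trip in sorted(table.R)
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_table(path: str | Path) -> PropensityTable:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "rbres-propensity-v1":
        raise ValueError("not a propensity table file")
    R = {t: np.array(d["R"]) for t, d in payload["triplets"].items()}
    I = {t: np.array(d["I"]) for t, d in payload["triplets"].items()}
    return PropensityTable(R=R, I=I, rsa_cutoff=payload["rsa_cutoff"],
                           n_chains=payload["n_chains"],
                           provenance=payload.get("provenance", {}))


def table_hash(table: PropensityTable) -> str:
    """Stable content hash used to stamp downstream artifacts."""
    h = hashlib.sha256()
    h.update(f"{table.rsa_cutoff}:{table.n_chains}".encode())
    for trip in sorted(table.R):
        h.update(trip.encode())
        h.update(np.asarray(table.R[trip]).tobytes())
        h.update(np.asarray(table.I.get(trip, np.zeros(3))).tobytes())
    return h.hexdigest()[:16]
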