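"""Classifier evaluation: confusion metrics, ROC/AUC, residue-level
cross-validation and the leave-one-feature-block-out ablation protocol.

Metrics follow the standard definitions

    SN  = TP/(TP+FN)            SP  = TN/(TN+FP)
    PPV = TP/(TP+FP)            ACC = (TP+TN)/total
    F   = 2TP/(2TP+FP+FN)
    MCC = (TP*TN - FP*FN)/sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

with zero-denominator ratios reported as 0 and flagged.  AUC is the area
under the ROC curve (trapezoidal over all thresholds), which equals the
concordance probability.  Cross-validation partitions *residues* at
random into k near-equal folds (the evaluation unit of the protocol this
package implements); a chain-grouped mode is available for stricter
evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

DEFAULT_THRESHOLD = 0.5


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, bool)
        y_pred = np.asarray(y_pred, bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)), tn=int(np.sum(~y_true & ~y_pred)),
            fp=int(np.sum(~y_true & y_pred)), fn=int(np.sum(y_true & ~y_pred)),
        )


@dataclass
class MetricsReport:
    sn: float
    sp: float
    ppv: float
    acc: float
    f_score: float
    mcc: float
    auc: Optional[float] = None
    threshold: float = DEFAULT_THRESHOLD
    degenerate: list[str] = field(default_factory=list)
    counts: Optional[ConfusionCounts] = None

    def as_dict(self) -> dict:
        d = {"SN": self.sn, "SP": self.sp, "PPV": self.ppv, "ACC": self.acc,
             "F_score": self.f_score, "MCC": self.mcc}
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts, threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """Confusion-based metric suite (AUC left unset)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    flags: list[str] = []
    sn = _ratio(tp, tp + fn, "SN", flags)
    sp = _ratio(tn, tn + fp, "SP", flags)
    ppv = _ratio(tp, tp + fp, "PPV", flags)
    acc = _ratio(tp + tn, counts.total, "ACC", flags)
    f = _ratio(2 * tp, 2 * tp + fp + fn, "F", flags)
    mcc_den = math.sqrt(float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        flags.append("MCC")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricsReport(sn=sn, sp=sp, ppv=ppv, acc=acc, f_score=f, mcc=mcc,
                         threshold=threshold, degenerate=flags, counts=counts)


def roc_auc(probabilities: np.ndarray, labels: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """(fpr, tpr, AUC); both classes must be present."""
    from sklearn.metrics import roc_curve, auc as sk_auc

    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(labels, probabilities)
    return fpr, tpr, float(sk_auc(fpr, tpr))


def evaluate_predictions(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> MetricsReport:
    counts = ConfusionCounts.from_predictions(labels, probabilities >= threshold)
    report = compute_metrics(counts, threshold)
    labels_b = np.asarray(labels, bool)
    if labels_b.any() and not labels_b.all():
        report.auc = roc_auc(probabilities, labels)[2]
    return report


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CvPlan:
    k: int = 5
    seed: int = 0
    group_by_chain: bool = False


@dataclass
class CvResult:
    fold_reports: list[MetricsReport]
    pooled: MetricsReport          # micro: pooled counts + pooled ROC
    macro: dict[str, float]        # fold-averaged metrics
    probabilities: np.ndarray      # out-of-fold, in input order
    fold_of: np.ndarray


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    plan: CvPlan | None = None,
    forest_params: Optional[dict] = None,
    groups: Optional[np.ndarray] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> CvResult:
    """k-fold CV of the random forest at the residue level.

    Every residue is tested exactly once; per-fold metrics plus pooled
    (micro) and fold-averaged (macro) summaries are reported.
    """
    from sklearn.model_selection import GroupKFold, KFold

    from .estimators import RnaBindingForest

    plan = plan or CvPlan()
    y = np.asarray(y, bool)
    if plan.k > len(y):
        raise ValueError("more folds than residues")
    if plan.group_by_chain:
        if groups is None:
            raise ValueError("chain-grouped CV requires group ids")
        splitter = GroupKFold(n_splits=plan.k)
        splits = splitter.split(X, y, groups)
    else:
        splitter = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
        splits = splitter.split(X)
    probs = np.zeros(len(y))
    fold_of = np.full(len(y), -1, int)
    fold_reports: list[MetricsReport] = []
    for fold, (train_idx, test_idx) in enumerate(splits):
        clf = RnaBindingForest(random_state=plan.seed, threshold=threshold,
                               **(forest_params or {}))
        clf.fit(X[train_idx], y[train_idx])
        p = clf.predict_proba(X[test_idx])[:, 1]
        probs[test_idx] = p
        fold_of[test_idx] = fold
        fold_reports.append(evaluate_predictions(p, y[test_idx], threshold))
    pooled = evaluate_predictions(probs, y, threshold)
    keys = ["SN", "SP", "PPV", "ACC", "F_score", "MCC", "AUC"]
    macro = {}
    for k in keys:
        vals = [r.as_dict().get(k) for r in fold_reports]
        vals = [v for v in vals if v is not None]
        if vals:
            macro[k] = float(np.mean(vals))
    return CvResult(fold_reports=fold_reports, pooled=pooled, macro=macro,
                    probabilities=probs, fold_of=fold_of)


# ---------------------------------------------------------------------------
# ablation

def ablation(
    X: np.ndarray,
    y: np.ndarray,
    layout,
    plan: CvPlan | None = None,
    forest_params: Optional[dict] = None,
    groups: Optional[np.ndarray] = None,
):
    """Feature-block contribution table.

    Rows: the full vector, each block left out, and each block alone;
    columns: the six confusion metrics + AUC from k-fold CV.  Returns a
    pandas DataFrame indexed by row name.
    """
    import pandas as pd

    plan = plan or CvPlan()
    rows: dict[str, dict] = {}

    def run(name: str, cols: np.ndarray) -> None:
        res = cross_validate(X[:, cols], y, plan, forest_params, groups)
        rows[name] = res.pooled.as_dict()

    all_cols = np.arange(X.shape[1])
    run("all_blocks", all_cols)
    for b in layout.blocks:
        cols = layout.columns_of(b.name)
        run(f"minus_{b.name}", np.setdiff1d(all_cols, cols))
        run(f"only_{b.name}", cols)
    return pd.DataFrame.from_dict(rows, orient="index")
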