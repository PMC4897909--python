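"""Confusion metrics, ROC/AUC and cross-validation machinery."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from rbres import evaluation as ev


def brute_force_metrics(tp, tn, fp, fn):
    """Independent evaluation of the six standard confusion metrics."""
    import math

    def div(a, b):
        return a / b if b else 0.0

    mcc_den = math.sqrt((tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    return {
        "SN": div(tp, tp + fn), "SP": div(tn, tn + fp), "PPV": div(tp, tp + fp),
        "ACC": div(tp + tn, tp + tn + fp + fn),
        "F_score": div(2 * tp, 2 * tp + fp + fn),
        "MCC": (tp * tn - fp * fn) / mcc_den if mcc_den else 0.0,
    }


def concordance_auc(probs, labels):
    """AUC as the probability that a positive outranks a negative."""
    pos = probs[labels]
    neg = probs[~labels]
    wins = ties = 0
    for p in pos:
        wins += np.sum(p > neg)
        ties += np.sum(p == neg)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# confusion metrics

def test_perfect_classifier_metrics():
    rep = ev.compute_metrics(ev.ConfusionCounts(5, 5, 0, 0))
    assert rep.sn == rep.sp == rep.ppv == rep.acc == rep.f_score == 1.0
    assert rep.mcc == 1.0 and not rep.degenerate


def test_worked_confusion_example():
    """TP=3 TN=5 FP=1 FN=1: SN .75, SP 5/6, PPV .75, ACC .8, F .75, MCC 14/24."""
    rep = ev.compute_metrics(ev.ConfusionCounts(3, 5, 1, 1))
    assert rep.sn == pytest.approx(0.75)
    assert rep.sp == pytest.approx(5 / 6)
    assert rep.ppv == pytest.approx(0.75)
    assert rep.acc == pytest.approx(0.8)
    assert rep.f_score == pytest.approx(0.75)
    assert rep.mcc == pytest.approx(14 / 24)


def test_degenerate_all_positive_predictor():
    rep = ev.compute_metrics(ev.ConfusionCounts(5, 0, 5, 0))
    assert rep.sn == 1.0 and rep.sp == 0.0
    assert rep.mcc == 0.0 and "MCC" in rep.degenerate


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ev.ConfusionCounts(-1, 0, 0, 0)


@given(hst.tuples(*[hst.integers(0, 500)] * 4))
def test_metrics_match_brute_force(counts):
    tp, tn, fp, fn = counts
    rep = ev.compute_metrics(ev.ConfusionCounts(tp, tn, fp, fn)).as_dict()
    for key, val in brute_force_metrics(tp, tn, fp, fn).items():
        assert rep[key] == pytest.approx(val, abs=1e-12)


# ---------------------------------------------------------------------------
# ROC / AUC

def test_auc_extremes_and_errors():
    labels = np.array([0, 0, 1, 1], bool)
    assert ev.roc_auc(labels.astype(float), labels)[2] == 1.0
    assert ev.roc_auc(1.0 - labels, labels)[2] == 0.0
    with pytest.raises(ValueError):
        ev.roc_auc(np.ones(3), np.ones(3, bool))


def test_auc_random_probabilities_near_half():
    rng = np.random.default_rng(42)
    probs = rng.uniform(size=10_000)
    labels = rng.uniform(size=10_000) < 0.5
    assert ev.roc_auc(probs, labels)[2] == pytest.approx(0.5, abs=0.03)


@pytest.mark.parametrize("trial", range(5))
def test_auc_equals_pairwise_concordance(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(10, 200))
    probs = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)   # force ties too
    labels = rng.uniform(size=n) < 0.4
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    auc = ev.roc_auc(probs, labels)[2]
    assert auc == pytest.approx(concordance_auc(probs, labels), abs=1e-12)


def test_evaluate_predictions_threshold():
    probs = np.array([0.9, 0.6, 0.4, 0.1])
    labels = np.array([1, 1, 0, 0], bool)
    rep = ev.evaluate_predictions(probs, labels, threshold=0.5)
    assert rep.counts.tp == 2 and rep.counts.tn == 2
    rep_hi = ev.evaluate_predictions(probs, labels, threshold=1.0)
    assert rep_hi.counts.tp == 0 and rep_hi.sn == 0.0


# ---------------------------------------------------------------------------
# cross-validation

def _separable(n=300, d=10, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 3 == 0
    X = rng.normal(size=(n, d))
    X[y, 0] += 4.0
    return X, y


def test_cv_partition_properties():
    X, y = _separable(1000)
    res = ev.cross_validate(X, y, ev.CvPlan(k=5, seed=1),
                            forest_params={"n_trees": 20})
    sizes = np.bincount(res.fold_of)
    assert len(sizes) == 5 and sizes.min() >= 199 and sizes.max() <= 201
    assert np.all(res.fold_of >= 0), "every residue tested exactly once"


def test_cv_separable_auc_and_determinism():
    X, y = _separable()
    r1 = ev.cross_validate(X, y, ev.CvPlan(k=5, seed=3),
                           forest_params={"n_trees": 50})
    assert r1.pooled.auc >= 0.95
    r2 = ev.cross_validate(X, y, ev.CvPlan(k=5, seed=3),
                           forest_params={"n_trees": 50})
    np.testing.assert_array_equal(r1.probabilities, r2.probabilities)
    np.testing.assert_array_equal(r1.fold_of, r2.fold_of)
    assert "AUC" in r1.macro and 0 <= r1.macro["AUC"] <= 1


def test_cv_robust_to_row_permutation():
    """Permuting the dataset rows (same seed policy) leaves the pooled
    out-of-fold AUC unchanged within tolerance."""
    X, y = _separable(400, seed=5)
    base = ev.cross_validate(X, y, ev.CvPlan(k=5, seed=2),
                             forest_params={"n_trees": 30}).pooled.auc
    perm = np.random.default_rng(1).permutation(len(y))
    permuted = ev.cross_validate(X[perm], y[perm], ev.CvPlan(k=5, seed=2),
                                 forest_params={"n_trees": 30}).pooled.auc
    assert abs(base - permuted) < 0.05


def test_cv_rejects_too_many_folds():
    X, y = _separable(10)
    with pytest.raises(ValueError):
        ev.cross_validate(X, y, ev.CvPlan(k=20))


def test_chain_grouped_cv_keeps_groups_intact():
    X, y = _separable(200)
    groups = np.repeat(np.arange(10), 20)
    res = ev.cross_validate(X, y, ev.CvPlan(k=5, group_by_chain=True),
                            forest_params={"n_trees": 20}, groups=groups)
    for g in range(10):
        assert len(set(res.fold_of[groups == g])) == 1


# ---------------------------------------------------------------------------
# ablation

def test_ablation_shape_and_zero_block():
    """11 rows (full + 5 leave-outs + 5 alones with a 5-block layout); an
    all-zero block neither helps nor hurts beyond CV noise."""
    from rbres.encoding import EncodingLayout, FeatureBlockSpec

    rng = np.random.default_rng(0)
    n = 240
    y = np.arange(n) % 3 == 0
    informative = rng.normal(size=(n, 4))
    informative[y, :2] += 3.0
    blocks = [FeatureBlockSpec("signal", 2, "sequential", 2),
              FeatureBlockSpec("zeros", 3, "sequential", 1)]
    X = np.hstack([informative, np.zeros((n, 3))])
    layout = EncodingLayout(blocks=blocks)
    table = ev.ablation(X, y, layout, ev.CvPlan(k=3, seed=0),
                        forest_params={"n_trees": 30})
    assert list(table.index) == ["all_blocks", "minus_signal", "only_signal",
                                 "minus_zeros", "only_zeros"]
    assert abs(table.loc["minus_zeros", "AUC"] - table.loc["all_blocks", "AUC"]) < 0.1
    assert table.loc["minus_signal", "AUC"] < table.loc["all_blocks", "AUC"] - 0.2
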