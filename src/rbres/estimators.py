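"""scikit-learn style estimators.

:class:`ResidueFeaturizer` is a transformer whose ``fit`` learns the
triplet interface propensity table from bound training complexes and
whose ``transform`` turns complexes (bound or apo) into the
patch-expanded residue feature matrix.  :class:`RnaBindingForest` is the
random-forest residue classifier (500 trees, sqrt(d) variables per
split — the conventional defaults).  Both compose with sklearn pipelines
and model selection.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .annotate import AnnotationConfig, ChainAnnotation, annotate_complex
from .encoding import FeatureBlockSpec, default_blocks, encode_dataset
from .propensity import PropensityTable, build_table_from_stats, table_hash
from .structure import Complex


class ResidueFeaturizer(BaseEstimator, TransformerMixin):
    """Complexes -> per-residue feature matrix.

    Parameters
    ----------
    binding_cutoff : float
        Heavy-atom/RNA distance (Å) defining RNA-binding residues in the
        training statistics (5.0 or 3.5 in the standard protocols).
    rsa_cutoff : float
        All-atom RSA (%) above which a residue counts as surface for
        triplet windows.
    probe, n_dots : surface generation parameters.
    eps, min_pts : DBSCAN parameters for the charged-patch clustering.
    blocks : optional list of FeatureBlockSpec overriding the default
        patch types/sizes.

    Attributes
    ----------
    propensity_table_ : PropensityTable learned in ``fit``.
    layout_ : EncodingLayout of the emitted matrix.
    n_features_out_ : int, total vector width (281 with defaults).
    """

    def __init__(
        self,
        binding_cutoff: float = 5.0,
        rsa_cutoff: float = 3.0,
        probe: float = 1.4,
        n_dots: int = 320,
        eps: float = 7.0,
        min_pts: int = 3,
        blocks: Optional[Sequence[FeatureBlockSpec]] = None,
    ):
        self.binding_cutoff = binding_cutoff
        self.rsa_cutoff = rsa_cutoff
        self.probe = probe
        self.n_dots = n_dots
        self.eps = eps
        self.min_pts = min_pts
        self.blocks = blocks

    # -- internals ----------------------------------------------------------

    def _config(self) -> AnnotationConfig:
        return AnnotationConfig(
            binding_cutoff=self.binding_cutoff, rsa_cutoff=self.rsa_cutoff,
            probe=self.probe, n_dots=self.n_dots, eps=self.eps,
            min_pts=self.min_pts,
        )

    def _annotate(self, X: Sequence) -> list[list[ChainAnnotation]]:
        cache = getattr(self, "_cache", None)
        if cache is None:
            cache = self._cache = {}
        out = []
        for item in X:
            if isinstance(item, list) and item and isinstance(item[0], ChainAnnotation):
                out.append(item)
                continue
            if not isinstance(item, Complex):
                raise TypeError("X must contain Complex objects (or annotations)")
            key = id(item)
            if key not in cache:
                cache[key] = annotate_complex(item, self._config())
            out.append(cache[key])
        return out

    # -- sklearn API --------------------------------------------------------

    def fit(self, X: Sequence[Complex], y=None) -> "ResidueFeaturizer":
        """Learn the propensity table from bound training complexes."""
        annotated = self._annotate(X)
        stats = [ann.stats() for anns in annotated for ann in anns]
        self.propensity_table_ = build_table_from_stats(
            stats, rsa_cutoff=self.rsa_cutoff,
            provenance={"binding_cutoff": self.binding_cutoff,
                        "rsa_cutoff": self.rsa_cutoff},
        )
        blocks = list(self.blocks) if self.blocks is not None else default_blocks()
        _, _, layout = encode_dataset(annotated[0], self.propensity_table_, blocks)
        self.layout_ = layout
        self.n_features_out_ = layout.total_width
        self.table_hash_ = table_hash(self.propensity_table_)
        return self

    def transform(self, X: Sequence[Complex]) -> np.ndarray:
        check_is_fitted(self, "propensity_table_")
        annotated = self._annotate(X)
        blocks = list(self.blocks) if self.blocks is not None else default_blocks()
        flat = [ann for anns in annotated for ann in anns]
        for ann in flat:
            ann.triplet = None   # re-derive against this featurizer's table
        Xmat, _, _ = encode_dataset(flat, self.propensity_table_, blocks)
        return Xmat

    def binding_labels(self, X: Sequence[Complex]) -> np.ndarray:
        """Ground-truth residue labels for bound complexes, matrix-row order."""
        annotated = self._annotate(X)
        labs = []
        for anns in annotated:
            for ann in anns:
                if ann.labels is None:
                    raise ValueError("apo complex has no binding labels")
                labs.append(ann.labels)
        return np.concatenate(labs).astype(bool)

    def chain_groups(self, X: Sequence[Complex]) -> np.ndarray:
        """Integer chain id per matrix row (for chain-grouped CV)."""
        annotated = self._annotate(X)
        groups, g = [], 0
        for anns in annotated:
            for ann in anns:
                groups.append(np.full(len(ann), g, int))
                g += 1
        return np.concatenate(groups)


class RnaBindingForest(BaseEstimator, ClassifierMixin):
    """Random-forest residue classifier.

    500 trees and sqrt(d) candidate variables per split by default; a
    fixed ``random_state`` makes fold assignment and predictions
    bit-reproducible.  ``predict`` thresholds the binding-class
    probability at ``threshold``.
    """

    def __init__(
        self,
        n_trees: int = 500,
        max_features: str | float = "sqrt",
        random_state: Optional[int] = None,
        threshold: float = 0.5,
        n_jobs: int = 1,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.random_state = random_state
        self.threshold = threshold
        self.n_jobs = n_jobs

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RnaBindingForest":
        X = np.asarray(X, float)
        y = np.asarray(y, bool)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, max_features=self.max_features,
            random_state=self.random_state, n_jobs=self.n_jobs,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        #: mean decrease in node impurity per feature
        self.feature_importances_ = self.forest_.feature_importances_
        return self

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature matrix has {X.shape[-1] if X.ndim else 0} columns; "
                f"model expects {self.n_features_in_}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forest_.predict_proba(self._check_X(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1] >= self.threshold

    def permutation_importance(self, X: np.ndarray, y: np.ndarray,
                               n_repeats: int = 5, random_state: int = 0):
        """Mean decrease in accuracy under feature permutation (on demand —
        the impurity importances are stored at fit time)."""
        from sklearn.inspection import permutation_importance as sk_pi

        return sk_pi(self.forest_, self._check_X(X), np.asarray(y, bool),
                     n_repeats=n_repeats, random_state=random_state,
                     n_jobs=self.n_jobs).importances_mean
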