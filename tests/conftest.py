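import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rbres.annotate import annotate_complex
from rbres.estimators import ResidueFeaturizer
from rbres.fixtures import (PlantedDatasetSpec, ToyComplexSpec,
                            generate_planted_dataset, toy_complex)

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy():
    """Default helix toy complex with its ground-truth labels."""
    return toy_complex(ToyComplexSpec(seed=0))


@pytest.fixture(scope="session")
def toy_annotation(toy):
    cx, _labels = toy
    return annotate_complex(cx)[0]


@pytest.fixture(scope="session")
def planted_small():
    """4-chain charge-biased dataset with the KRG triplet planted."""
    return generate_planted_dataset(PlantedDatasetSpec(n_chains=4, seed=11))


@pytest.fixture(scope="session")
def planted_featurized(planted_small):
    feat = ResidueFeaturizer()
    feat.fit(planted_small.complexes)
    X = feat.transform(planted_small.complexes)
    y = feat.binding_labels(planted_small.complexes)
    return feat, X, y


# ---------------------------------------------------------------------------
# independent oracles

def dbscan_oracle(points: np.ndarray, eps: float, min_pts: int):
    """Brute-force density clustering: ε-graph connected components over core
    points (≥ min_pts neighbors within eps, self included); border points
    attach to any neighboring core cluster; the rest is noise (-1).

    Returns (labels, core_mask).  Border-point cluster choice is ambiguous by
    construction, so comparisons must only pin down cores and noise.
    """
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts
    labels = np.full(n, -1, int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in np.nonzero(neigh[j])[0]:
                if core[k] and labels[k] == -1:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    for i in range(n):     # border points
        if labels[i] == -1 and not core[i]:
            cores_near = [j for j in np.nonzero(neigh[i])[0] if core[j]]
            if cores_near:
                labels[i] = labels[cores_near[0]]
    return labels, core


def assert_same_clustering(labels_a, labels_b, core, neigh_eps, points):
    """Equality up to label permutation on cores and noise; border points may
    sit in any cluster that owns one of their core neighbors."""
    import collections

    noise_a = labels_a == -1
    noise_b = labels_b == -1
    assert np.array_equal(noise_a, noise_b), "noise sets differ"
    # cores: identical partition up to relabeling
    mapping = {}
    for i in np.nonzero(core)[0]:
        la, lb = labels_a[i], labels_b[i]
        assert la != -1 and lb != -1
        if la in mapping:
            assert mapping[la] == lb, "core partition differs"
        else:
            mapping[la] = lb
    assert len(set(mapping.values())) == len(mapping), "core clusters merged"
    # border points: cluster must contain a core neighbor in both labelings
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    for i in np.nonzero(~core & ~noise_a)[0]:
        for labels in (labels_a, labels_b):
            owners = {labels[j] for j in np.nonzero(d[i] <= neigh_eps)[0] if core[j]}
            assert labels[i] in owners, "border point not attached to a neighbor"
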