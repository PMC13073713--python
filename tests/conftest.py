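import numpy as np
import pytest

from riskstack.features import FeatureTable
from riskstack.synthetic import GeneratorConfig, generate_inspection_records


@pytest.fixture(scope="session")
def records_792():
    """Study-scale synthetic table: 792 rows, class counts (279, 458, 55)."""
    return generate_inspection_records(GeneratorConfig(n_records=792, seed=7))


@pytest.fixture(scope="session")
def records_small():
    return generate_inspection_records(
        GeneratorConfig(n_records=120, class_proportions=(0.4, 0.4, 0.2), seed=3)
    )


@pytest.fixture
def separable_ft():
    """60 rows, 3 well-separated Gaussian blobs (20 per class)."""
    rng = np.random.default_rng(0)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    X = np.vstack([rng.normal(c, 0.3, size=(20, 2)) for c in centers])
    y = np.repeat([0, 1, 2], 20)
    return FeatureTable(X, y, ["f0", "f1"])


def brute_force_tomek(X, y):
    """All-pairs mutual-nearest-neighbour scan (O(n^2)), ties to lower index."""
    n = len(X)
    nn = []
    for i in range(n):
        best, best_d = None, np.inf
        for j in range(n):
            if j == i:
                continue
            d = float(np.linalg.norm(X[i] - X[j]))
            if d < best_d:
                best, best_d = j, d
        nn.append(best)
    return sorted(
        (i, nn[i])
        for i in range(n)
        if nn[nn[i]] == i and y[i] != y[nn[i]] and i < nn[i]
    )


def pair_count_auc(positive, scores):
    """Mann-Whitney concordant/tied pair counting oracle."""
    pos = scores[positive]
    neg = scores[~positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
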