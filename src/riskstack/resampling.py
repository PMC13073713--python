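"""Hybrid resampling: per-class bootstrap, SMOTE interpolation and
Tomek-link boundary cleaning on encoded feature tables.

Distances are plain Euclidean on the encoded matrix (one-hot and bounded
cyclical terms only, so no rescaling is applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from riskstack.features import FeatureTable


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    target: str = "majority"  # balance every class up to the majority count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target != "majority":
            raise ValueError(f"unknown balancing policy {self.target!r}")


def smote_oversample(
    X_minority: np.ndarray, n_new: int, cfg: SmoteConfig
) -> np.ndarray:
    """Synthesize ``n_new`` rows by linear interpolation between a random
    minority row and one of its k nearest same-class neighbours:
    ``x_new = x_i + lam * (x_j - x_i)`` with ``lam ~ U(0, 1)``.

    The neighbour count shrinks to ``rows - 1`` for tiny classes; a
    single-row class falls back to exact duplication with a warning.
    """
    X_minority = np.atleast_2d(np.asarray(X_minority, dtype=float))
    n_rows = X_minority.shape[0]
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if n_rows == 0:
        raise ValueError("cannot oversample an empty class")
    if n_new == 0:
        return np.empty((0, X_minority.shape[1]))
    rng = np.random.default_rng(cfg.seed)
    if n_rows == 1:
        warnings.warn(
            "single-row class: synthetic rows are exact duplicates",
            stacklevel=2,
        )
        return np.repeat(X_minority, n_new, axis=0)

    k = min(cfg.k_neighbors, n_rows - 1)
    dist = cdist(X_minority, X_minority)
    np.fill_diagonal(dist, np.inf)
    # k nearest same-class neighbours per row; stable sort -> lower index wins ties
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, :k]

    base = rng.integers(n_rows, size=n_new)
    picked = neighbours[base, rng.integers(k, size=n_new)]
    lam = rng.random(n_new)[:, None]
    return X_minority[base] + lam * (X_minority[picked] - X_minority[base])


def find_tomek_links(X: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """All unordered cross-class mutual-nearest-neighbour pairs.

    Nearest neighbour is computed over the whole table under Euclidean
    distance (self excluded, distance ties broken toward the lower index);
    pairs are returned sorted by (min index, max index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    nn = np.argmin(dist, axis=1)  # argmin returns the first (lowest) index on ties
    links = [
        (i, int(nn[i]))
        for i in range(n)
        if nn[nn[i]] == i and y[i] != y[nn[i]] and i < nn[i]
    ]
    return sorted(links)


def _balance_targets(counts: dict[int, int]) -> dict[int, int]:
    majority = max(counts.values())
    return {c: majority for c in counts}


def smote_tomek_balance(ft: FeatureTable, cfg: SmoteConfig) -> FeatureTable:
    """SMOTE every non-majority class up to the majority count, then clean
    Tomek links on the augmented table.

    For each link, the member whose class has the larger current row count
    is removed (counts updated as links are processed in index order); a
    count tie removes neither member, so a fully balanced table is never
    un-balanced by more than the links it sheds.
    """
    classes, class_counts = np.unique(ft.y, return_counts=True)
    counts = dict(zip(classes.tolist(), class_counts.tolist()))
    targets = _balance_targets(counts)

    X_parts = [ft.X]
    y_parts = [ft.y]
    for offset, c in enumerate(classes.tolist()):
        n_new = targets[c] - counts[c]
        if n_new == 0:
            continue
        synth = smote_oversample(
            ft.X[ft.y == c], n_new, replace(cfg, seed=cfg.seed + offset)
        )
        X_parts.append(synth)
        y_parts.append(np.full(n_new, c, dtype=int))
    X_aug = np.vstack(X_parts)
    y_aug = np.concatenate(y_parts)

    current = {c: int((y_aug == c).sum()) for c in classes.tolist()}
    removed: set[int] = set()
    for i, j in find_tomek_links(X_aug, y_aug):
        ci, cj = int(y_aug[i]), int(y_aug[j])
        if current[ci] > current[cj]:
            removed.add(i)
            current[ci] -= 1
        elif current[cj] > current[ci]:
            removed.add(j)
            current[cj] -= 1
    keep = np.array([i for i in range(len(y_aug)) if i not in removed])
    return FeatureTable(X_aug[keep], y_aug[keep], list(ft.column_names))


def stratified_bootstrap(ft: FeatureTable, seed: int) -> FeatureTable:
    """Bootstrap within each class, preserving per-class counts exactly."""
    classes = np.unique(ft.y)
    if classes.size == 0:
        raise ValueError("empty table")
    rng = np.random.default_rng(seed)
    idx_parts = []
    for c in classes:
        members = np.flatnonzero(ft.y == c)
        idx_parts.append(rng.choice(members, size=members.size, replace=True))
    idx = np.concatenate(idx_parts)
    return FeatureTable(ft.X[idx], ft.y[idx], list(ft.column_names))
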