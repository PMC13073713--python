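import numpy as np
import pytest

from conftest import brute_force_tomek
from riskstack.features import FeatureTable
from riskstack.resampling import (
    SmoteConfig,
    find_tomek_links,
    smote_oversample,
    smote_tomek_balance,
    stratified_bootstrap,
)


class TestSmote:
    def test_two_points_synthetics_on_segment(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        out = smote_oversample(X, 5, SmoteConfig(seed=1))
        assert out.shape == (5, 2)
        # every synthetic is (t, t) with 0 <= t <= 2
        np.testing.assert_allclose(out[:, 0], out[:, 1])
        assert np.all(out >= 0.0) and np.all(out <= 2.0)

    def test_identical_rows_give_identical_synthetics(self):
        X = np.tile([1.5, -2.0, 3.0], (4, 1))
        out = smote_oversample(X, 6, SmoteConfig(seed=0))
        np.testing.assert_allclose(out, np.tile([1.5, -2.0, 3.0], (6, 1)))

    def test_zero_requested_gives_empty(self):
        out = smote_oversample(np.ones((3, 2)), 0, SmoteConfig())
        assert out.shape == (0, 2)

    def test_single_row_duplicates_with_warning(self):
        with pytest.warns(UserWarning, match="single-row"):
            out = smote_oversample(np.array([[1.0, 2.0]]), 3, SmoteConfig())
        np.testing.assert_array_equal(out, np.tile([1.0, 2.0], (3, 1)))

    def test_empty_class_errors(self):
        with pytest.raises(ValueError, match="empty"):
            smote_oversample(np.empty((0, 2)), 1, SmoteConfig())

    def test_seeded_determinism(self):
        X = np.random.default_rng(3).normal(size=(10, 4))
        a = smote_oversample(X, 20, SmoteConfig(seed=5))
        b = smote_oversample(X, 20, SmoteConfig(seed=5))
        np.testing.assert_array_equal(a, b)

    def test_synthetics_are_convex_combinations(self):
        """Each synthetic solves x_new = x_i + lam*(x_j - x_i) for some
        original pair and lam in [0, 1]."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 3))
        out = smote_oversample(X, 30, SmoteConfig(k_neighbors=3, seed=2))
        for row in out:
            ok = False
            for i in range(len(X)):
                for j in range(len(X)):
                    if i == j:
                        continue
                    diff = X[j] - X[i]
                    lam = np.dot(row - X[i], diff) / np.dot(diff, diff)
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(
                        row, X[i] + lam * diff, atol=1e-9
                    ):
                        ok = True
            assert ok


class TestTomekLinks:
    def test_two_far_clusters_no_links(self):
        X = np.vstack([np.random.default_rng(0).normal(0, 0.1, (5, 2)),
                       np.random.default_rng(1).normal(100, 0.1, (5, 2))])
        y = np.array([0] * 5 + [1] * 5)
        assert find_tomek_links(X, y) == []

    def test_one_point_per_class_is_a_link(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        assert find_tomek_links(X, np.array([0, 1])) == [(0, 1)]

    def test_1d_fixture_against_brute_force(self):
        X = np.array([[0.0], [1.0], [1.1]])
        y = np.array([0, 0, 1])
        links = find_tomek_links(X, y)
        assert links == brute_force_tomek(X, y) == [(1, 2)]

    def test_agrees_with_brute_force_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(4, 31))
            d = int(rng.integers(1, 6))
            X = rng.normal(size=(n, d)).round(2)  # rounding forces some ties
            y = rng.integers(0, 3, size=n)
            assert find_tomek_links(X, y) == brute_force_tomek(X, y)

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            find_tomek_links(np.ones((1, 2)), np.array([0]))


def _ft(X, y):
    X = np.asarray(X, dtype=float)
    return FeatureTable(X, y, [f"f{i}" for i in range(X.shape[1])])


class TestSmoteTomekBalance:
    def test_balanced_separated_input_unchanged(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(c, 0.1, (5, 2)) for c in (0.0, 50.0, 100.0)])
        y = np.repeat([0, 1, 2], 5)
        out = smote_tomek_balance(_ft(X, y), SmoteConfig(seed=1))
        np.testing.assert_array_equal(out.X, X)
        np.testing.assert_array_equal(out.y, y)

    def test_counts_raised_to_majority(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(20, 1, (5, 3)),
                       rng.normal(-20, 1, (2, 3))])
        y = np.array([0] * 10 + [1] * 5 + [2] * 2)
        out = smote_tomek_balance(_ft(X, y), SmoteConfig(seed=2))
        # separated classes: no links, so counts are exactly (10, 10, 10)
        assert np.bincount(out.y).tolist() == [10, 10, 10]

    def test_matches_hand_composition_of_sub_operations(self):
        """Reference run: compose smote_oversample + find_tomek_links + the
        removal rule outside the implementation (30-row fixture, seed=3)."""
        rng = np.random.default_rng(30)
        X = np.vstack([rng.normal(0, 1.5, (18, 2)), rng.normal(1, 1.5, (9, 2)),
                       rng.normal(2, 1.5, (3, 2))])
        y = np.array([0] * 18 + [1] * 9 + [2] * 3)
        cfg = SmoteConfig(seed=3)
        out = smote_tomek_balance(_ft(X, y), cfg)

        # reference composition
        from dataclasses import replace

        parts_X, parts_y = [X], [y]
        for offset, c in enumerate([0, 1, 2]):
            n_new = 18 - int((y == c).sum())
            if n_new:
                parts_X.append(
                    smote_oversample(X[y == c], n_new, replace(cfg, seed=cfg.seed + offset))
                )
                parts_y.append(np.full(n_new, c))
        X_aug = np.vstack(parts_X)
        y_aug = np.concatenate(parts_y)
        current = {c: int((y_aug == c).sum()) for c in (0, 1, 2)}
        removed = set()
        for i, j in find_tomek_links(X_aug, y_aug):
            ci, cj = int(y_aug[i]), int(y_aug[j])
            if current[ci] > current[cj]:
                removed.add(i); current[ci] -= 1
            elif current[cj] > current[ci]:
                removed.add(j); current[cj] -= 1
        keep = [i for i in range(len(y_aug)) if i not in removed]
        assert out.n_rows == len(keep)
        np.testing.assert_array_equal(out.X, X_aug[keep])
        np.testing.assert_array_equal(out.y, y_aug[keep])

    def test_never_removes_smallest_class_and_ratio_bound(self):
        rng = np.random.default_rng(99)
        for trial in range(10):
            n0, n1, n2 = rng.integers(3, 15, size=3)
            X = rng.normal(size=(n0 + n1 + n2, 2))
            y = np.array([0] * n0 + [1] * n1 + [2] * n2)
            out = smote_tomek_balance(_ft(X, y), SmoteConfig(seed=trial))
            counts = np.bincount(out.y, minlength=3)
            smallest = int(np.argmin([n0, n1, n2]))
            majority = max(n0, n1, n2)
            # the globally smallest class keeps its full post-SMOTE count
            assert counts[smallest] == majority
            # Tomek can only trim larger-count classes
            assert counts.max() / counts.min() <= 1.0 + 1e-12


class TestStratifiedBootstrap:
    def test_preserves_per_class_counts(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(792, 3))
        y = np.array([2] * 55 + [1] * 458 + [0] * 279)
        out = stratified_bootstrap(_ft(X, y), seed=5)
        assert np.bincount(out.y).tolist() == [279, 458, 55]
        assert out.n_rows == 792

    def test_single_row_per_class_identity(self):
        X = np.arange(6.0).reshape(3, 2)
        y = np.array([0, 1, 2])
        out = stratified_bootstrap(_ft(X, y), seed=1)
        assert sorted(map(tuple, out.X.tolist())) == sorted(map(tuple, X.tolist()))

    def test_unique_fraction_matches_bootstrap_identity(self):
        """Mean unique fraction over 200 seeds at n=100 approximates
        1 - (1 - 1/n)^n ~ 0.634."""
        X = np.arange(100.0)[:, None]
        y = np.zeros(100, dtype=int)
        ft = _ft(X, y)
        fractions = [
            len(np.unique(stratified_bootstrap(ft, seed=s).X)) / 100
            for s in range(200)
        ]
        assert 0.60 <= np.mean(fractions) <= 0.67

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        ft = _ft(rng.normal(size=(30, 2)), rng.integers(0, 3, 30))
        a = stratified_bootstrap(ft, seed=7)
        b = stratified_bootstrap(ft, seed=7)
        np.testing.assert_array_equal(a.X, b.X)
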