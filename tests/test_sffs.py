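"""Scored SFFS: cluster quality, pass bookkeeping, ranking behavior."""

import itertools

import numpy as np
import pytest

from dbmorph.features import FeatureDescriptor, FeatureMatrix
from dbmorph.sffs import (
    cluster_quality,
    sffs_score,
    sffs_single_run,
    top_k,
)


# --- independent references, written against the documented behavior ---

def quality_reference(X, y):
    """Plain-numpy re-derivation of the deterministic 2-means quality."""
    X = np.asarray(X, float)
    n = len(y)
    majority = max(np.sum(y), n - np.sum(y)) / n
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    best, bi, bj = 0.0, 0, 0
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] > best:
                best, bi, bj = d2[i, j], i, j
    if best <= 1e-24:
        return majority
    a = np.where(d2[:, bi] <= d2[:, bj], 0, 1)
    for _ in range(100):
        if (a == 0).sum() in (0, n):
            break
        c0, c1 = X[a == 0].mean(0), X[a == 1].mean(0)
        na = np.where(((X - c0) ** 2).sum(1) <= ((X - c1) ** 2).sum(1), 0, 1)
        if np.array_equal(na, a):
            break
        a = na
    agree = (a == y).mean()
    return max(agree, 1 - agree)


def sffs_run_reference(X, y, ordering):
    """Forward/backward pass bookkeeping re-derived with the reference quality."""
    n, d = X.shape
    majority = max(np.sum(y), n - np.sum(y)) / n
    deltas = np.zeros(d, int)
    subset = []
    q = majority
    for idx in ordering:
        subset.append(idx)
        qp = quality_reference(X[:, subset], y)
        deltas[idx] += 1 if qp > q else -1
        q = qp
    for idx in ordering:
        subset.remove(idx)
        qp = majority if not subset else quality_reference(X[:, subset], y)
        deltas[idx] += 1 if qp < q else -1
        q = qp
    return deltas


def brute_force_two_means(X):
    """Globally optimal 2-means partition by exhaustive enumeration."""
    n = len(X)
    best_ss, best_assign = np.inf, None
    for bits in itertools.product([0, 1], repeat=n - 1):
        a = np.array((0,) + bits)
        if a.min() == a.max():
            continue
        ss = 0.0
        for k in (0, 1):
            pts = X[a == k]
            ss += ((pts - pts.mean(0)) ** 2).sum()
        if ss < best_ss:
            best_ss, best_assign = ss, a
    return best_assign


LAB6 = np.array(["a", "a", "a", "b", "b", "b"])


class TestClusterQuality:
    def test_perfectly_separated(self):
        x = np.array([[0], [0], [0], [10], [10], [10]], float)
        assert cluster_quality(x, LAB6) == 1.0

    def test_assignment_invariant(self):
        x = np.array([[0], [0], [0], [10], [10], [10]], float)
        assert cluster_quality(x, LAB6[::-1]) == 1.0

    def test_degenerate_identical_rows_gives_majority(self):
        x = np.ones((6, 2))
        assert cluster_quality(x, LAB6) == 0.5
        labels = np.array(["a", "a", "b", "b", "b", "b"])
        assert cluster_quality(x, labels) == 4 / 6

    def test_matches_brute_force_on_separated_2d(self):
        """Hand-set 2D rows: Lloyd from farthest pair reaches the optimum."""
        x = np.array([[0.0, 0.2], [0.3, -0.1], [-0.2, 0.0],
                      [5.0, 5.1], [5.2, 4.8], [4.9, 5.3]])
        a = brute_force_two_means(x)
        agree = max((a == (LAB6 == "b")).mean(), (a != (LAB6 == "b")).mean())
        assert cluster_quality(x, LAB6) == agree == 1.0

    def test_matches_reference_implementation(self, rng):
        for _ in range(50):
            n, k = rng.integers(4, 12), rng.integers(1, 4)
            X = rng.normal(size=(n, k))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            got = cluster_quality(X, y)
            want = quality_reference(X, (y == np.unique(y)[1]).astype(int))
            assert got == pytest.approx(want, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cluster_quality(np.ones((4, 1)), np.array(["a"] * 4))


class TestSingleRun:
    def test_perfect_feature_scores_plus_two(self):
        x = np.array([[0], [0], [0], [10], [10], [10]], float)
        deltas = sffs_single_run(x, LAB6, ordering=np.array([0]))
        assert deltas.tolist() == [2]

    def test_constant_feature_scores_minus_two(self):
        deltas = sffs_single_run(np.ones((6, 1)), LAB6, ordering=np.array([0]))
        assert deltas.tolist() == [-2]

    def test_invalid_ordering_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            sffs_single_run(X, LAB6, ordering=np.array([0, 1, 1]))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            sffs_single_run(np.empty((6, 0)), LAB6, ordering=np.array([], int))

    def test_deltas_bounded(self, rng):
        X = rng.normal(size=(8, 6))
        y = np.array(["a", "b"] * 4)
        deltas = sffs_single_run(X, y, ordering=rng.permutation(6))
        assert set(np.unique(deltas)).issubset({-2, 0, 2})

    def test_matches_reference_trace(self, rng):
        """Kernel agrees with an independent pure-python pass re-derivation."""
        for _ in range(20):
            n, d = 8, int(rng.integers(2, 6))
            X = rng.normal(size=(n, d))
            y01 = rng.integers(0, 2, size=n)
            if y01.min() == y01.max():
                y01[0] = 1 - y01[0]
            labels = np.where(y01 == 1, "z", "a")
            ordering = rng.permutation(d)
            got = sffs_single_run(X, labels, ordering=ordering)
            want = sffs_run_reference(X, y01, ordering)
            assert np.array_equal(got, want)


class TestScore:
    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.normal(size=(10, 8))
        y = np.array(["a", "b"] * 5)
        a = sffs_score(X, y, n_runs=20, seed=3)
        b = sffs_score(X, y, n_runs=20, seed=3)
        assert np.array_equal(a.scores, b.scores)

    def test_single_run_composition(self, rng):
        X = rng.normal(size=(10, 5))
        y = np.array(["a", "b"] * 5)
        s = sffs_score(X, y, n_runs=1, seed=9)
        ordering = np.random.default_rng(9).permutation(5)
        assert np.array_equal(s.scores, sffs_single_run(X, y, ordering))

    def test_score_bound(self, rng):
        X = rng.normal(size=(10, 6))
        y = np.array(["a", "b"] * 5)
        s = sffs_score(X, y, n_runs=25, seed=0)
        assert np.abs(s.scores).max() <= 2 * 25

    def test_zero_runs_rejected(self, rng):
        with pytest.raises(ValueError):
            sffs_score(rng.normal(size=(6, 3)), LAB6, n_runs=0, seed=0)

    def test_planted_feature_outranks_noise(self):
        """A perfectly separating feature wins against 19 noise features."""
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((20, 20))
            lab = np.array([0] * 10 + [1] * 10)
            X[:, 7] = -2.0 + 4.0 * lab + 0.25 * r.standard_normal(20)
            s = sffs_score(X, lab, n_runs=250, seed=seed)
            wins += top_k(s, 1)[0].column == 7
        assert wins >= 19

    def test_planted_mean_score_margin(self):
        """Ordering-invariance in the limit: planted mean beats noise means."""
        n_runs = 100
        planted, noise = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((20, 20))
            lab = np.array([0] * 10 + [1] * 10)
            X[:, 7] = -2.0 + 4.0 * lab + 0.25 * r.standard_normal(20)
            s = sffs_score(X, lab, n_runs=n_runs, seed=seed)
            planted.append(s.scores[7])
            noise.append(np.delete(s.scores, 7).max())
        margin = np.mean(planted) - np.mean(noise)
        assert margin >= 0.5 * n_runs


class TestTopK:
    def _scores(self, values):
        from dbmorph.sffs import FeatureScores

        desc = [FeatureDescriptor(0, j, "magnitude", 1.0)
                for j in range(len(values))]
        return FeatureScores(np.array(values), 1, 0, desc)

    def test_descending_selection(self):
        tops = top_k(self._scores([5, 3, 9]), k=2)
        assert [t.column for t in tops] == [2, 0]

    def test_tie_break_by_column(self):
        tops = top_k(self._scores([1, 1, 1, 1, 1, 1]), k=5)
        assert [t.column for t in tops] == [0, 1, 2, 3, 4]

    def test_k_equals_feature_count(self):
        tops = top_k(self._scores([2, -1, 4]), k=3)
        assert [t.column for t in tops] == [2, 0, 1]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            top_k(self._scores([1, 2]), k=3)


def test_brute_force_best_feature_in_top3(rng):
    """On small instances the single best feature lands in the SFFS top-3."""
    hits = 0
    n_seeds = 30
    for seed in range(n_seeds):
        r = np.random.default_rng(1000 + seed)
        n, d = 10, 8
        X = r.standard_normal((n, d))
        y = np.array([0] * 5 + [1] * 5)
        X[:, seed % d] += 2.5 * y  # one informative feature per instance
        labels = np.where(y == 1, "dis", "ctl")
        qualities = np.array([cluster_quality(X[:, [j]], labels)
                              for j in range(d)])
        best_set = set(np.flatnonzero(qualities == qualities.max()))
        s = sffs_score(X, labels, n_runs=100, seed=seed)
        hits += bool(best_set & {t.column for t in top_k(s, 3)})
    assert hits >= 0.9 * n_seeds


def test_scores_csv(tmp_path, rng):
    X = rng.normal(size=(6, 4))
    desc = [FeatureDescriptor(0, j, "magnitude", 3.0) for j in range(4)]
    mat = FeatureMatrix(X, desc, LAB6)
    s = sffs_score(mat, n_runs=5, seed=1)
    s.to_csv(tmp_path / "scores.csv")
    import pandas as pd

    df = pd.read_csv(tmp_path / "scores.csv")
    assert len(df) == 4 and "score" in df.columns and "feature" in df.columns
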