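"""Numba kernels for the feature-scoring inner loops.

The SFFS passes evaluate 2-means cluster quality thousands of times on
nested feature subsets.  All cluster computations here run on the Gram
matrix of the subjects restricted to the current subset: squared
distances between subjects and cluster centroids depend only on inner
products, and adding/removing one feature is a rank-1 Gram update.  Each
quality evaluation is therefore O(n_subjects^2) regardless of how many
features the subset holds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["quality_from_gram", "sffs_run_kernel"]


@njit(cache=True)
def quality_from_gram(G: np.ndarray, y: np.ndarray) -> float:
    """2-means label-agreement quality from a subject Gram matrix.

    Deterministic farthest-pair initialization (ties broken by lowest row
    index pair), Lloyd iterations to an assignment fixed point (cap 100),
    ties in assignment go to cluster 0.  Quality is the fraction of
    subjects whose cluster matches their label, maximized over the two
    cluster-to-label pairings.  If all rows coincide the quality is the
    majority-label fraction.
    """
    n = G.shape[0]
    n1 = 0
    for i in range(n):
        n1 += y[i]
    majority = max(n1, n - n1) / n

    # farthest pair seeding
    best = 0.0
    bi, bj = 0, 0
    for i in range(n):
        for j in range(i + 1, n):
            d = G[i, i] + G[j, j] - 2.0 * G[i, j]
            if d > best:
                best = d
                bi, bj = i, j
    if best <= 1e-24:  # all rows identical in this subspace
        return majority

    a = np.empty(n, np.int8)
    for i in range(n):
        d0 = G[i, i] - 2.0 * G[i, bi] + G[bi, bi]
        d1 = G[i, i] - 2.0 * G[i, bj] + G[bj, bj]
        a[i] = 0 if d0 <= d1 else 1

    s1_0 = np.empty(n)
    s1_1 = np.empty(n)
    for _ in range(100):
        m0 = 0
        for i in range(n):
            if a[i] == 0:
                m0 += 1
        m1 = n - m0
        if m0 == 0 or m1 == 0:
            break
        s2_0 = 0.0
        s2_1 = 0.0
        for i in range(n):
            acc0 = 0.0
            acc1 = 0.0
            for j in range(n):
                if a[j] == 0:
                    acc0 += G[i, j]
                else:
                    acc1 += G[i, j]
            s1_0[i] = acc0
            s1_1[i] = acc1
            if a[i] == 0:
                s2_0 += acc0
            else:
                s2_1 += acc1
        changed = False
        for i in range(n):
            cost0 = -2.0 * s1_0[i] / m0 + s2_0 / (m0 * m0)
            cost1 = -2.0 * s1_1[i] / m1 + s2_1 / (m1 * m1)
            na = 0 if cost0 <= cost1 else 1
            if na != a[i]:
                changed = True
            a[i] = na
        if not changed:
            break

    agree = 0
    for i in range(n):
        if a[i] == y[i]:
            agree += 1
    frac = agree / n
    return max(frac, 1.0 - frac)


@njit(cache=True)
def sffs_run_kernel(
    X: np.ndarray, y: np.ndarray, ordering: np.ndarray
) -> np.ndarray:
    """One scored SFFS run: forward add pass then backward remove pass.

    Forward: starting from an empty subset with quality q = majority
    fraction, each feature (in ``ordering``) is added and stays in; its
    delta is +1 if the subset quality strictly improved, else -1, and q
    tracks the new quality.  Backward: starting from the full subset and
    its quality, each feature is removed in the same order; its delta is
    +1 if quality strictly dropped without it, else -1, with q updated
    after each removal (empty subset counts as majority fraction).
    """
    n, d = X.shape
    deltas = np.zeros(d, np.int64)
    G = np.zeros((n, n))
    n1 = 0
    for i in range(n):
        n1 += y[i]
    majority = max(n1, n - n1) / n

    q = majority
    for k in range(d):
        idx = ordering[k]
        for i in range(n):
            xi = X[i, idx]
            for j in range(n):
                G[i, j] += xi * X[j, idx]
        qp = quality_from_gram(G, y)
        deltas[idx] += 1 if qp > q else -1
        q = qp

    for k in range(d):
        idx = ordering[k]
        for i in range(n):
            xi = X[i, idx]
            for j in range(n):
                G[i, j] -= xi * X[j, idx]
        if k == d - 1:
            qp = majority
        else:
            qp = quality_from_gram(G, y)
        deltas[idx] += 1 if qp < q else -1
        q = qp
    return deltas
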