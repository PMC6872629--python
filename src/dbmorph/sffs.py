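"""Scored sequential floating forward selection (SFFS) of features.

Features are judged by how much they help a simple unsupervised
classifier — 2-means clustering — agree with the true class labels.  One
run walks a random ordering of all features twice: a forward pass adds
each feature to a growing subset (+1 to its score if the cluster quality
strictly improves, -1 otherwise), then a backward pass removes each
feature from the shrinking subset (+1 if quality drops without it, -1
otherwise).  Scores are summed over many independent random orderings
(default 250) to wash out ordering effects, and the top-k features
(default 5) become the candidate biomarkers.

This is the scored variant of SFFS, not the classical dynamic
subset-size algorithm: every feature is visited exactly twice per run,
so per-run deltas lie in {-2, 0, +2} and |score| <= 2 * n_runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import quality_from_gram, sffs_run_kernel
from .features import FeatureDescriptor, FeatureMatrix

__all__ = [
    "FeatureScores",
    "TopFeature",
    "cluster_quality",
    "sffs_single_run",
    "sffs_score",
    "top_k",
]


@dataclass
class FeatureScores:
    """Accumulated per-feature SFFS scores."""

    scores: np.ndarray
    n_runs: int
    ordering_seed: int
    descriptors: list[FeatureDescriptor] | None = field(default=None)

    def to_csv(self, path: str | Path) -> None:
        rows = {"column": np.arange(len(self.scores)), "score": self.scores}
        if self.descriptors is not None:
            rows["feature"] = [d.name for d in self.descriptors]
            rows["grid_row"] = [d.grid_row for d in self.descriptors]
            rows["grid_col"] = [d.grid_col for d in self.descriptors]
            rows["channel"] = [d.channel for d in self.descriptors]
            rows["cell_size"] = [d.cell_size for d in self.descriptors]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class TopFeature:
    column: int
    score: int
    descriptor: FeatureDescriptor | None = None


def _binary_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(
            f"need exactly 2 classes among the labels, got {classes.size}"
        )
    return (labels == classes[1]).astype(np.int8)


def cluster_quality(X_subset: np.ndarray, labels: np.ndarray) -> float:
    """Agreement of deterministic 2-means clusters with the class labels.

    Centroids are seeded with the two rows at maximal Euclidean distance
    (ties by lowest row index) and Lloyd iterations run to an assignment
    fixed point (cap 100).  The returned quality in [0, 1] is the matched
    fraction maximized over the two cluster-to-label pairings; if all rows
    are identical it is the majority-label fraction.
    """
    X_subset = np.atleast_2d(np.asarray(X_subset, dtype=np.float64))
    if X_subset.shape[1] < 1:
        raise ValueError("need at least one feature column")
    y = _binary_labels(labels)
    if X_subset.shape[0] != y.size or y.size < 2:
        raise ValueError("need one label per subject and at least 2 subjects")
    G = X_subset @ X_subset.T
    return float(quality_from_gram(np.ascontiguousarray(G), y))


def _matrix_and_labels(
    X: FeatureMatrix | np.ndarray, labels: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, FeatureMatrix):
        values = X.values
        if labels is None:
            labels = X.labels
    else:
        values = np.asarray(X, dtype=np.float64)
        if labels is None:
            raise ValueError("labels are required when X is a bare array")
    if values.ndim != 2 or values.shape[1] == 0:
        raise ValueError("feature matrix must be 2D with at least one column")
    return values, np.asarray(labels)


def sffs_single_run(
    X: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    ordering: np.ndarray | None = None,
) -> np.ndarray:
    """Per-feature score deltas of one forward+backward pass.

    ``ordering`` must be a permutation of all column indices.  Each
    feature is touched once per pass, so its delta is in {-2, 0, +2}.
    """
    values, labels = _matrix_and_labels(X, labels)
    if ordering is None:
        raise ValueError("an explicit feature ordering is required")
    ordering = np.asarray(ordering, dtype=np.int64)
    d = values.shape[1]
    if sorted(ordering.tolist()) != list(range(d)):
        raise ValueError("ordering must be a permutation of all column indices")
    y = _binary_labels(labels)
    return np.asarray(
        sffs_run_kernel(np.ascontiguousarray(values), y, ordering)
    )


def sffs_score(
    X: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    n_runs: int = 250,
    seed: int = 0,
) -> FeatureScores:
    """Sum single-run deltas over ``n_runs`` random feature orderings.

    Orderings are drawn from a generator seeded by ``seed``; the result is
    deterministic for a fixed seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    values, labels_arr = _matrix_and_labels(X, labels)
    y = _binary_labels(labels_arr)
    d = values.shape[1]
    rng = np.random.default_rng(seed)
    total = np.zeros(d, dtype=np.int64)
    values_c = np.ascontiguousarray(values)
    for _ in range(n_runs):
        ordering = rng.permutation(d).astype(np.int64)
        total += sffs_run_kernel(values_c, y, ordering)
    descriptors = X.descriptors if isinstance(X, FeatureMatrix) else None
    return FeatureScores(total, n_runs, seed, descriptors)


def top_k(scores: FeatureScores, k: int = 5) -> list[TopFeature]:
    """The k highest-scoring features, descending score, ties by column."""
    d = len(scores.scores)
    if k > d:
        raise ValueError(f"k={k} exceeds feature count {d}")
    order = np.lexsort((np.arange(d), -scores.scores))
    out = []
    for col in order[:k]:
        desc = scores.descriptors[col] if scores.descriptors is not None else None
        out.append(TopFeature(int(col), int(scores.scores[col]), desc))
    return out
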