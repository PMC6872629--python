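"""PCA noise suppression on cohort feature matrices.

The cohort feature matrix (observations = subjects, variables = per-cell
deformation features) is decomposed into principal components; the
smallest set of leading components explaining at least the requested
fraction of total variance (default 95%) is retained and the matrix is
reconstructed back in the original feature space.  The discarded trailing
variance is treated as noise.  Feature selection downstream therefore
still operates on per-location features, not on component scores.

Columns are mean-centered but not scaled to unit variance; covariance
uses the n-1 denominator.  Implemented directly via SVD so the degenerate
cases (constant columns, zero-variance matrices, fraction = 1.0) have
explicit, documented behavior; agreement with scikit-learn's PCA is
checked in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import FeatureMatrix

__all__ = ["PCAResult", "pca_denoise"]


@dataclass
class PCAResult:
    """Retained orthonormal basis and the denoised feature matrix.

    ``components`` has shape (n_retained, n_features);
    ``explained_fraction`` holds the per-component variance fractions of
    *all* components (non-increasing), of which the first ``n_retained``
    were kept.
    """

    components: np.ndarray
    explained_fraction: np.ndarray
    n_retained: int
    mean: np.ndarray
    reconstructed: FeatureMatrix

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path, components=self.components, mean=self.mean,
            explained_fraction=self.explained_fraction,
        )
        path.with_suffix(".json").write_text(
            json.dumps(
                {"n_retained": self.n_retained,
                 "n_features": int(self.mean.size)},
                sort_keys=True,
            )
        )


def pca_denoise(X: FeatureMatrix, variance_fraction: float = 0.95) -> PCAResult:
    """Project onto the leading principal components and reconstruct.

    ``n_retained`` is the smallest k whose cumulative explained variance
    reaches ``variance_fraction``; the reconstruction keeps the original
    shape, descriptors and labels.  A matrix with zero total variance
    retains no components and reconstructs to itself (the column means).
    """
    if not (0 < variance_fraction <= 1):
        raise ValueError("variance_fraction must be in (0, 1]")
    values = X.values
    n = values.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 subjects")

    mean = values.mean(axis=0)
    centered = values - mean
    # thin SVD: centered = U S Vt, component variances S^2 / (n - 1)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    variances = s**2 / (n - 1)
    total = variances.sum()
    if total <= 0:
        fractions = np.zeros_like(variances)
        k = 0
    else:
        fractions = variances / total
        cumulative = np.cumsum(fractions)
        # tolerance absorbs float round-off when fraction == 1.0
        k = int(np.searchsorted(cumulative, variance_fraction - 1e-12) + 1)
        k = min(k, len(fractions))
    components = vt[:k]
    scores = centered @ components.T
    recon = scores @ components + mean
    reconstructed = FeatureMatrix(recon, list(X.descriptors), X.labels.copy())
    return PCAResult(components, fractions, k, mean, reconstructed)
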