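"""SVM validation of candidate features with repeated leave-n-out ROC.

The selected features are validated with an RBF-kernel support vector
machine under repeated random leave-5-out cross-validation: each round
holds out 5 subjects, trains on the rest (features standardized with
training statistics only), scores the held-out subjects, and contributes
one empirical ROC curve.  Curves are vertically averaged on a fixed
101-point FPR grid; the mean TPR, its across-round variance per grid
point, and the trapezoidal AUC of the mean curve summarize performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "SVMParams",
    "SVMModel",
    "ROCCurve",
    "train_svm",
    "leave_n_out_roc",
    "auc",
    "roc_points",
    "plot_roc",
]


@dataclass
class SVMParams:
    C: float = 1.0
    gamma: float | str = "scale"  # 1 / (n_features * feature variance)


@dataclass
class SVMModel:
    """Trained SVM plus the training-set standardization it relies on.

    Sign convention: positive decision scores mean the diseased class.
    """

    svc: SVC
    mean: np.ndarray
    sd: np.ndarray
    classes: np.ndarray  # (negative label, positive label)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=np.float64) - self.mean) / self.sd
        return self.svc.decision_function(Xs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0,
                        self.classes[1], self.classes[0])


def _as_binary(y: np.ndarray, pos_label=None) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if pos_label is not None:
        if pos_label not in classes:
            raise ValueError(f"pos_label {pos_label!r} not among classes")
        classes = np.array([c for c in classes if c != pos_label] + [pos_label])
    return (y == classes[1]).astype(int), classes


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    params: SVMParams | None = None,
    pos_label=None,
) -> SVMModel:
    """Fit an RBF SVM on training subjects (standardized per feature).

    Standardization statistics come from the training set only and travel
    with the model (zero-variance features get sd 1, contributing a
    constant after centering).
    """
    params = params or SVMParams()
    X = np.asarray(X, dtype=np.float64)
    yb, classes = _as_binary(y, pos_label)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mean) / sd
    svc = SVC(kernel="rbf", C=params.C, gamma=params.gamma)
    svc.fit(Xs, yb)
    return SVMModel(svc, mean, sd, classes)


def auc(roc_pts) -> float:
    """Trapezoidal area under ROC points.

    Points are sorted by FPR; (0, 0) is prepended and (1, 1) appended.
    All coordinates must lie in [0, 1].
    """
    pts = np.asarray(roc_pts, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected a list of (fpr, tpr) pairs")
    if np.any(pts < 0) or np.any(pts > 1):
        raise ValueError("ROC coordinates must lie in [0, 1]")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    fpr = np.concatenate([[0.0], pts[:, 0], [1.0]])
    tpr = np.concatenate([[0.0], pts[:, 1], [1.0]])
    return float(np.trapezoid(tpr, fpr))


def roc_points(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Empirical ROC step points (fpr, tpr) of a score vector."""
    from sklearn.metrics import roc_curve

    yb, _ = _as_binary(y)
    fpr, tpr, _ = roc_curve(yb, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


@dataclass
class ROCCurve:
    """Vertically averaged ROC over cross-validation rounds."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    tpr_variance: np.ndarray
    auc: float
    n_rounds: int
    n_rejected: int = 0
    n_skipped: int = 0

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"fpr": self.fpr_grid, "mean_tpr": self.mean_tpr,
             "tpr_variance": self.tpr_variance}
        ).to_csv(path, index=False, float_format="%.17g")

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "n_rounds": self.n_rounds,
            "n_rejected_splits": self.n_rejected,
            "n_skipped_single_class_tests": self.n_skipped,
        }

    def save_summary(self, path: str | Path, extra: dict | None = None) -> None:
        payload = self.summary()
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _round_tpr_on_grid(
    scores: np.ndarray, yb: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """One round's empirical ROC evaluated at the FPR grid (step curve).

    TPR at grid value f is the best TPR achievable at FPR <= f, i.e. the
    value of the empirical ROC step function.
    """
    pos = scores[yb == 1]
    neg = scores[yb == 0]
    thresholds = np.unique(scores)  # predict positive when score >= t
    fpr = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    tpr = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    # thresholds ascending -> fpr/tpr non-increasing; flip to ascending fpr
    fpr = np.concatenate([fpr[::-1], [1.0]])
    tpr = np.concatenate([tpr[::-1], [1.0]])
    idx = np.searchsorted(fpr, grid, side="right") - 1
    out = np.maximum.accumulate(tpr)[np.clip(idx, 0, None)]
    out[idx < 0] = 0.0
    return out


def leave_n_out_roc(
    X: np.ndarray,
    y: np.ndarray,
    n_test: int = 5,
    n_rounds: int = 1000,
    seed: int = 0,
    params: SVMParams | None = None,
    pos_label=None,
) -> ROCCurve:
    """Repeated random leave-``n_test``-out cross-validation ROC.

    Each round samples ``n_test`` subjects without replacement as the test
    set (splits with a single-class training set are rejected and
    redrawn; rounds whose *test* set is single-class are drawn but skipped
    in the averaging since their TPR or FPR is undefined).  Per round the
    held-out decision scores give a TPR at each of 101 FPR grid points;
    the mean and variance across rounds and the trapezoidal AUC of the
    mean curve are returned.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=np.float64)
    yb, classes = _as_binary(y, pos_label)
    n = len(yb)
    if n_test >= n:
        raise ValueError("n_test must be smaller than the number of subjects")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    n_rejected = 0
    n_skipped = 0
    for _ in range(n_rounds):
        for _attempt in range(1000):
            test_idx = rng.choice(n, size=n_test, replace=False)
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            if len(np.unique(yb[train_mask])) == 2:
                break
            n_rejected += 1
        else:
            raise RuntimeError("all candidate splits had single-class training sets")
        if len(np.unique(yb[test_idx])) < 2:
            n_skipped += 1
            continue
        model = train_svm(X[train_mask], yb[train_mask], params)
        scores = model.decision_function(X[test_idx])
        tprs.append(_round_tpr_on_grid(scores, yb[test_idx], grid))
    if not tprs:
        raise RuntimeError("no cross-validation round had both classes in its test set")
    tpr_arr = np.vstack(tprs)
    mean_tpr = tpr_arr.mean(axis=0)
    var_tpr = tpr_arr.var(axis=0)
    area = float(np.trapezoid(mean_tpr, grid))
    return ROCCurve(grid, mean_tpr, var_tpr, area, len(tprs), n_rejected, n_skipped)


def plot_roc(curves: dict[str, ROCCurve], path: str | Path) -> None:
    """Mean ROC curves with +-1 sd bands and AUC in the legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for name, curve in curves.items():
        sd = np.sqrt(curve.tpr_variance)
        ax.plot(curve.fpr_grid, curve.mean_tpr,
                label=f"{name} (AUC = {curve.auc:.2f})")
        ax.fill_between(curve.fpr_grid, curve.mean_tpr - sd,
                        np.minimum(curve.mean_tpr + sd, 1.0), alpha=0.15)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False-positive rate (1 - specificity)")
    ax.set_ylabel("True-positive rate (sensitivity)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
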