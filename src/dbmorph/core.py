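"""Core containers shared across the pipeline.

Coordinate convention: 0-based ``(row, col)`` with row increasing downward.
Displacement fields live on the reference grid and *pull*: a field ``u``
maps reference grid point ``x`` to the query-image location ``x + u(x)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["GrayImage", "DeformationField", "AffineTransform2D"]


@dataclass
class GrayImage:
    """A 2D grayscale image with pixel geometry.

    Parameters
    ----------
    pixels : ndarray
        2D float array of intensities.
    spacing : float
        Physical size of a pixel in mm (1.0 when unknown).
    subject_id : str or None
        Opaque identifier of the subject the image belongs to.
    """

    pixels: np.ndarray
    spacing: float = 1.0
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage requires a non-empty 2D pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("GrayImage intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self) -> "GrayImage":
        return GrayImage(self.pixels.copy(), self.spacing, self.subject_id)


@dataclass
class DeformationField:
    """Dense per-grid-point displacement vectors on the reference grid.

    ``u`` has shape ``(rows, cols, 2)`` storing ``(d_row, d_col)`` in pixels.
    ``cell_size`` is the edge length, in original reference pixels, of one
    grid cell (1.0 before downsampling).  The all-zero field is the identity
    mapping.
    """

    u: np.ndarray
    cell_size: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 3 or self.u.shape[2] != 2:
            raise ValueError("DeformationField.u must have shape (rows, cols, 2)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("DeformationField components must be finite")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.u.shape[:2]  # type: ignore[return-value]

    def copy(self) -> "DeformationField":
        return DeformationField(self.u.copy(), self.cell_size, dict(self.meta))

    def save(self, path: str | Path) -> None:
        """Write the field as a compressed array with a JSON sidecar."""
        path = Path(path)
        np.savez_compressed(path, u=self.u)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "grid_shape": list(self.grid_shape),
                    "cell_size": self.cell_size,
                    "convention": "reference-pull",
                    "meta": {k: v for k, v in self.meta.items()},
                },
                sort_keys=True,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "DeformationField":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        with np.load(path) as data:
            u = data["u"]
        sidecar = path.with_suffix(".json")
        cell_size, meta = 1.0, {}
        if sidecar.exists():
            info = json.loads(sidecar.read_text())
            cell_size = float(info.get("cell_size", 1.0))
            meta = info.get("meta", {})
        return cls(u, cell_size, meta)


@dataclass
class AffineTransform2D:
    """A 2D affine point map ``y = A (x - c) + c + t`` in (row, col) coords.

    The map takes *query* coordinates to *reference* coordinates: applying
    it to the query image content aligns the query with the reference.
    ``center`` is the rotation/shear pivot (usually the image center).
    """

    linear: np.ndarray
    translation: np.ndarray
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=np.float64).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(2)
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=np.float64).reshape(2)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("affine linear part must be invertible")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (row, col) points."""
        pts = np.asarray(pts, dtype=np.float64)
        c = np.zeros(2) if self.center is None else self.center
        return (pts - c) @ self.linear.T + c + self.translation
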