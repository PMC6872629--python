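"""Deformation-field feature channels and cohort feature matrices.

A subject's deformation field is converted into per-cell scalar channels:
the polar decomposition of the displacement (magnitude m and direction d
of each cell's vector) and the Jacobian determinant of the deformation
(local area change: 1 = none, <1 shrinkage, >1 expansion).  Fields are
first downsampled onto coarser grids (default cells of 3, 3.75 and 5
pixels) to smooth over residual misalignment; each rate is analyzed
independently.

Direction is a circular variable.  By default it is handed downstream as
the pair (sin d, cos d) so Euclidean distances are continuous across ±π;
the raw-angle representation is available via ``direction_encoding``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import DeformationField

__all__ = [
    "PolarField",
    "JacobianMap",
    "FeatureDescriptor",
    "FeatureMatrix",
    "downsample_field",
    "field_to_polar",
    "jacobian_determinant",
    "build_feature_matrix",
]

CHANNELS = ("magnitude", "direction", "jacobian")


@dataclass
class PolarField:
    """Per-cell displacement length (px) and angle in (-pi, pi] radians."""

    magnitude: np.ndarray
    direction: np.ndarray
    cell_size: float = 1.0


@dataclass
class JacobianMap:
    """Per-cell determinant of I + ∇u (dimensionless area-change factor)."""

    detJ: np.ndarray
    cell_size: float = 1.0


class FeatureDescriptor(NamedTuple):
    """Ties one feature-matrix column back to a grid cell and channel."""

    grid_row: int
    grid_col: int
    channel: str
    cell_size: float

    @property
    def name(self) -> str:
        return f"r{self.grid_row}c{self.grid_col}_{self.channel}_s{self.cell_size:g}"


@dataclass
class FeatureMatrix:
    """Subjects x features with one descriptor per column."""

    values: np.ndarray
    descriptors: list[FeatureDescriptor]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("FeatureMatrix.values must be 2D")
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("column count must equal descriptor count")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("row count must equal label count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write values as CSV (named columns) plus a descriptor sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.values, columns=[d.name for d in self.descriptors])
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False, float_format="%.17g")
        sidecar = path.with_suffix(".descriptors.json")
        sidecar.write_text(
            json.dumps([d._asdict() for d in self.descriptors], sort_keys=True)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        labels = df.pop("label").to_numpy()
        sidecar = path.with_suffix(".descriptors.json")
        descriptors = [
            FeatureDescriptor(**d) for d in json.loads(sidecar.read_text())
        ]
        return cls(df.to_numpy(dtype=np.float64), descriptors, labels)


def _overlap_weights(n_fine: int, cell: float) -> np.ndarray:
    """1D (n_coarse, n_fine) matrix of interval-overlap lengths.

    Fine pixel i covers [i, i+1); coarse cell k covers [k*cell, (k+1)*cell).
    Entry (k, i) is the length of their intersection, so a row gives the
    area weights of one coarse cell.  Exact block selection for integer
    cells.
    """
    n_coarse = math.ceil(n_fine / cell)
    w = np.zeros((n_coarse, n_fine))
    for k in range(n_coarse):
        lo, hi = k * cell, (k + 1) * cell
        i0, i1 = int(math.floor(lo)), min(n_fine, int(math.ceil(hi)))
        for i in range(i0, i1):
            w[k, i] = max(0.0, min(hi, i + 1) - max(lo, i))
    return w


def downsample_field(field: DeformationField, cell: float) -> DeformationField:
    """Area-weighted block mean of the field on a coarser grid.

    The coarse grid has ``ceil(rows/cell) x ceil(cols/cell)`` cells; each
    coarse vector is the area-weighted mean of the fine vectors its cell
    overlaps (an exact block mean when ``cell`` is an integer).  Handles
    fractional cells such as 3.75 by box-filter resampling.
    """
    if cell < 1:
        raise ValueError("cell size must be >= 1")
    if cell == 1:
        return field.copy()
    rows, cols = field.grid_shape
    w_r = _overlap_weights(rows, cell)
    w_c = _overlap_weights(cols, cell)
    area = np.outer(w_r.sum(axis=1), w_c.sum(axis=1))
    coarse = np.stack(
        [w_r @ field.u[..., k] @ w_c.T / area for k in range(2)], axis=-1
    )
    return DeformationField(coarse, cell_size=cell * field.cell_size)


def field_to_polar(field: DeformationField) -> PolarField:
    """Polar decomposition: magnitude and direction ``atan2(u_row, u_col)``.

    The zero vector maps to (0, 0) by convention.
    """
    u_r, u_c = field.u[..., 0], field.u[..., 1]
    magnitude = np.hypot(u_r, u_c)
    direction = np.arctan2(u_r, u_c)
    direction = np.where(magnitude == 0, 0.0, direction)
    return PolarField(magnitude, direction, field.cell_size)


def jacobian_determinant(field: DeformationField) -> JacobianMap:
    """Determinant of the deformation Jacobian, det(I + ∇u), per cell.

    Gradients use central differences (one-sided at borders) with the
    grid's physical cell size as spacing.  Identity field → 1 everywhere;
    values below 1 indicate shrinkage, above 1 expansion.
    """
    rows, cols = field.grid_shape
    if rows < 3 or cols < 3:
        raise ValueError("Jacobian needs a grid of at least 3x3 cells")
    h = field.cell_size
    du_r_dr, du_r_dc = np.gradient(field.u[..., 0], h)
    du_c_dr, du_c_dc = np.gradient(field.u[..., 1], h)
    det = (1.0 + du_r_dr) * (1.0 + du_c_dc) - du_r_dc * du_c_dr
    return JacobianMap(det, field.cell_size)


def _channel_maps(
    field: DeformationField,
    channels: Sequence[str],
    direction_encoding: str,
) -> list[tuple[str, np.ndarray]]:
    maps: list[tuple[str, np.ndarray]] = []
    polar = None
    for ch in channels:
        if ch == "magnitude":
            polar = polar or field_to_polar(field)
            maps.append(("magnitude", polar.magnitude))
        elif ch == "direction":
            polar = polar or field_to_polar(field)
            if direction_encoding == "sincos":
                maps.append(("direction_sin", np.sin(polar.direction)))
                maps.append(("direction_cos", np.cos(polar.direction)))
            elif direction_encoding == "angle":
                maps.append(("direction", polar.direction))
            else:
                raise ValueError(
                    f"unknown direction_encoding {direction_encoding!r}"
                )
        elif ch == "jacobian":
            maps.append(("jacobian", jacobian_determinant(field).detJ))
        else:
            raise ValueError(f"unknown channel {ch!r}; choose from {CHANNELS}")
    return maps


def build_feature_matrix(
    fields: Sequence[DeformationField],
    labels: Sequence[str],
    rates: Sequence[float],
    channels: Sequence[str] = ("magnitude", "direction"),
    direction_encoding: str = "sincos",
) -> dict[float, FeatureMatrix]:
    """Assemble one feature matrix per downsampling rate.

    For each rate every field is downsampled, the requested channels are
    computed on the coarse grid, and cells are flattened row-major with
    channels interleaved per cell (magnitude, direction, jacobian order as
    requested).  Rates are analyzed independently, so per-rate matrices
    stay separate.
    """
    if len(fields) != len(labels):
        raise ValueError("need one label per field")
    if not fields:
        raise ValueError("need at least one field")
    shape0 = fields[0].grid_shape
    for f in fields:
        if f.grid_shape != shape0 or f.cell_size != fields[0].cell_size:
            raise ValueError("all fields must share the reference grid")

    out: dict[float, FeatureMatrix] = {}
    for rate in rates:
        rows_list: list[np.ndarray] = []
        descriptors: list[FeatureDescriptor] | None = None
        for f in fields:
            coarse = downsample_field(f, rate)
            maps = _channel_maps(coarse, channels, direction_encoding)
            gr, gc = coarse.grid_shape
            if descriptors is None:
                descriptors = [
                    FeatureDescriptor(r, c, name, coarse.cell_size)
                    for r in range(gr)
                    for c in range(gc)
                    for name, _ in maps
                ]
            cell_stack = np.stack([m for _, m in maps], axis=-1)  # (gr, gc, ch)
            rows_list.append(cell_stack.reshape(-1))
        assert descriptors is not None
        out[rate] = FeatureMatrix(
            np.vstack(rows_list), descriptors, np.asarray(labels)
        )
    return out
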