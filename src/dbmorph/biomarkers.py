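"""Mapping selected features back to pixel regions on the reference image.

A feature descriptor names a cell of a downsampled grid; mapped back to
the reference it becomes a half-open pixel rectangle.  Rectangles of one
rate tile the reference without overlap (floor-based interval arithmetic)
and are clipped at the image edge.  Overlays draw rectangle outlines in a
per-rate color (default: red for 3 px cells, green for 3.75, cyan for 5)
over the grayscale reference so underlying structure stays visible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import GrayImage
from .features import FeatureDescriptor

__all__ = [
    "BiomarkerEntry",
    "BiomarkerSet",
    "map_features_to_reference",
    "render_overlay",
    "localization_error",
    "DEFAULT_RATE_COLORS",
]

DEFAULT_RATE_COLORS: dict[float, tuple[int, int, int]] = {
    3.0: (255, 0, 0),  # red
    3.75: (0, 255, 0),  # green
    5.0: (0, 255, 255),  # cyan
}
_FALLBACK_COLORS = [(255, 0, 255), (255, 255, 0), (0, 0, 255), (255, 128, 0)]


@dataclass
class BiomarkerEntry:
    descriptor: FeatureDescriptor
    rect: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    score: float = 0.0

    @property
    def center(self) -> tuple[float, float]:
        r0, c0, r1, c1 = self.rect
        return ((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0)


@dataclass
class BiomarkerSet:
    entries: list[BiomarkerEntry]
    rate_colors: dict[float, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_RATE_COLORS)
    )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "feature": e.descriptor.name,
                "grid_row": e.descriptor.grid_row,
                "grid_col": e.descriptor.grid_col,
                "channel": e.descriptor.channel,
                "cell_size": e.descriptor.cell_size,
                "r0": e.rect[0], "c0": e.rect[1],
                "r1": e.rect[2], "c1": e.rect[3],
                "score": e.score,
            }
            for e in self.entries
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"descriptor": e.descriptor._asdict(), "rect": list(e.rect),
             "score": e.score}
            for e in self.entries
        ]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def cell_rectangle(
    row: int, col: int, cell: float, shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    """Half-open pixel rectangle of grid cell (row, col) at cell size ``cell``.

    Rows span [floor(row*cell), floor((row+1)*cell)), likewise for
    columns, clipped to the image bounds — so the cells of one rate
    partition the image.
    """
    r0, r1 = math.floor(row * cell), math.floor((row + 1) * cell)
    c0, c1 = math.floor(col * cell), math.floor((col + 1) * cell)
    return (
        max(0, r0), max(0, c0),
        min(shape[0], r1), min(shape[1], c1),
    )


def map_features_to_reference(
    descriptors: Sequence[FeatureDescriptor],
    reference_shape: tuple[int, int],
    scores: Sequence[float] | None = None,
) -> BiomarkerSet:
    """Map feature descriptors to pixel rectangles on the reference."""
    entries = []
    scores = list(scores) if scores is not None else [0.0] * len(descriptors)
    for desc, score in zip(descriptors, scores):
        s = desc.cell_size
        n_rows = math.ceil(reference_shape[0] / s)
        n_cols = math.ceil(reference_shape[1] / s)
        if not (0 <= desc.grid_row < n_rows and 0 <= desc.grid_col < n_cols):
            raise ValueError(
                f"descriptor {desc.name} outside the {n_rows}x{n_cols} grid "
                f"implied by reference shape {reference_shape}"
            )
        rect = cell_rectangle(desc.grid_row, desc.grid_col, s, reference_shape)
        entries.append(BiomarkerEntry(desc, rect, float(score)))
    return BiomarkerSet(entries)


def _outline_mask(rect: tuple[int, int, int, int],
                  shape: tuple[int, int]) -> np.ndarray:
    r0, c0, r1, c1 = rect
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    inner = np.zeros(shape, dtype=bool)
    inner[r0 + 1:max(r0 + 1, r1 - 1), c0 + 1:max(c0 + 1, c1 - 1)] = True
    return mask & ~inner


def render_overlay(
    reference: GrayImage,
    sets: Sequence[BiomarkerSet],
    path: str | Path,
) -> np.ndarray:
    """Write the reference with colored biomarker rectangle outlines.

    Returns the rendered RGB array (uint8).  Pixels outside the outlines
    are exactly the grayscale reference; output is deterministic.
    """
    gray = np.clip(np.round(reference.pixels * 255.0), 0, 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    for bset in sets:
        for entry in bset.entries:
            rate = entry.descriptor.cell_size
            color = bset.rate_colors.get(rate)
            if color is None:
                idx = hash(rate) % len(_FALLBACK_COLORS)
                color = _FALLBACK_COLORS[idx]
            mask = _outline_mask(entry.rect, reference.shape)
            rgb[mask] = color
    iio.imwrite(Path(path), rgb)
    return rgb


def localization_error(
    biomarkers: BiomarkerSet,
    lesion_centers: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Distance from each biomarker rectangle center to the nearest lesion."""
    if len(lesion_centers) == 0:
        raise ValueError("need at least one lesion center")
    centers = np.asarray(lesion_centers, dtype=np.float64)
    out = np.empty(len(biomarkers.entries))
    for i, entry in enumerate(biomarkers.entries):
        rc = np.asarray(entry.center)
        out[i] = np.sqrt(((centers - rc) ** 2).sum(axis=1)).min()
    return out
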