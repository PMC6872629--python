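"""Loading, cropping, normalization and reference-subject selection.

The registration stages assume every image is a normalized 2D grayscale
slice on a common grid.  This module reads single-frame DICOM and 8/16-bit
PNG, crops away empty background, rescales intensities robustly into
[0, 1], and picks the "most average-looking" subject of a cohort from a
table of scalar morphometric measurements to serve as the registration
reference.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

from .core import GrayImage

__all__ = [
    "load_image",
    "load_manifest",
    "crop_and_normalize",
    "select_reference",
]

logger = logging.getLogger(__name__)

_PNG_SUFFIXES = {".png"}
_DICOM_SUFFIXES = {".dcm", ".dicom"}
_ARRAY_SUFFIXES = {".npy", ".npz"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in _PNG_SUFFIXES:
        return "png"
    if suffix in _DICOM_SUFFIXES:
        return "dicom"
    if suffix in _ARRAY_SUFFIXES:
        return "array"
    raise ValueError(f"cannot infer image format from suffix {suffix!r}: {path}")


def load_image(path: str | Path, format: str | None = None) -> GrayImage:
    """Load a single 2D grayscale image.

    ``format`` is one of ``dicom``, ``png`` or ``array`` (inferred from the
    file suffix when omitted).  Intensities are returned as floats without
    rescaling; pixel spacing is taken from DICOM ``PixelSpacing`` metadata
    when present and defaults to 1.0 otherwise.  Multi-frame inputs are
    rejected: select and export a single slice first.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    fmt = format or _infer_format(path)
    spacing = 1.0
    if fmt == "png":
        arr = np.asarray(iio.imread(path), dtype=np.float64)
    elif fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
        if n_frames > 1:
            raise ValueError(
                f"{path} holds {n_frames} frames; select a single slice "
                "(e.g. the midsagittal one) before loading"
            )
        arr = np.asarray(ds.pixel_array, dtype=np.float64)
        if getattr(ds, "PixelSpacing", None) is not None:
            spacing = float(ds.PixelSpacing[0])
    elif fmt == "array":
        loaded = np.load(path)
        if isinstance(loaded, np.lib.npyio.NpzFile):
            arr = np.asarray(loaded[loaded.files[0]], dtype=np.float64)
        else:
            arr = np.asarray(loaded, dtype=np.float64)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) PNG → luminance
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single 2D frame, got array of shape {arr.shape}"
        )
    return GrayImage(arr, spacing=spacing, subject_id=path.stem)


def load_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (subject_id, label, image_path, ...)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "label", "image_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def auto_crop_bbox(image: GrayImage, pad: int = 5) -> tuple[int, int, int, int]:
    """Bounding box (r0, c0, r1, c1) of the largest foreground component.

    Foreground is everything above the Otsu threshold; the box is padded by
    ``pad`` pixels and clipped to the image bounds.
    """
    px = image.pixels
    if px.max() == px.min():
        return (0, 0, px.shape[0], px.shape[1])
    thr = threshold_otsu(px)
    labeled = measure.label(px > thr)
    if labeled.max() == 0:
        return (0, 0, px.shape[0], px.shape[1])
    regions = measure.regionprops(labeled)
    largest = max(regions, key=lambda r: r.area)
    r0, c0, r1, c1 = largest.bbox
    return (
        max(0, r0 - pad),
        max(0, c0 - pad),
        min(px.shape[0], r1 + pad),
        min(px.shape[1], c1 + pad),
    )


def crop_and_normalize(
    image: GrayImage,
    bbox: tuple[int, int, int, int] | None = None,
) -> GrayImage:
    """Crop to the object and rescale intensities into [0, 1].

    ``bbox`` is ``(r0, c0, r1, c1)`` half-open in pixel coordinates; when
    omitted the box is found automatically (Otsu threshold, largest
    connected component, 5 px pad).  Intensities are mapped linearly so the
    1st/99th percentiles land on 0/1 and then clipped; a constant image
    yields all zeros with a logged warning.
    """
    px = image.pixels
    if bbox is None:
        bbox = auto_crop_bbox(image)
    r0, c0, r1, c1 = bbox
    if not (0 <= r0 < r1 <= px.shape[0] and 0 <= c0 < c1 <= px.shape[1]):
        raise ValueError(f"bbox {bbox} outside image bounds {px.shape}")
    cropped = px[r0:r1, c0:c1]
    lo, hi = np.percentile(cropped, [1.0, 99.0])
    # snap near-normalized endpoints so normalization is idempotent: a prior
    # pass leaves the 1st/99th percentiles within clip-mass rounding of 0/1
    if abs(lo) < 5e-3:
        lo = 0.0
    if abs(hi - 1.0) < 5e-3:
        hi = 1.0
    if hi <= lo:
        logger.warning(
            "constant image %s: normalization returns all zeros", image.subject_id
        )
        return GrayImage(np.zeros_like(cropped), image.spacing, image.subject_id)
    out = np.clip((cropped - lo) / (hi - lo), 0.0, 1.0)
    return GrayImage(out, image.spacing, image.subject_id)


def select_reference(table: pd.DataFrame) -> str:
    """Pick the most average-looking subject from morphometric measurements.

    ``table`` is indexed by subject id (or has a ``subject_id`` column) with
    one numeric column per measurement.  Each subject is scored by the sum
    over measurements of ``|value - cohort mean| / cohort sd`` (sd taken as
    1 when zero, so constant measurements contribute nothing); the subject
    with the smallest score wins, ties broken by row order.  Standardizing
    makes the score invariant to per-measurement rescaling.
    """
    df = table.copy()
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    if len(df) < 2:
        raise ValueError("need at least 2 subjects to select a reference")
    values = df.to_numpy(dtype=np.float64)
    if values.size == 0:
        raise ValueError("need at least 1 measurement column")
    if not np.all(np.isfinite(values)):
        raise ValueError("morphometric table contains missing/non-finite values")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    scores = (np.abs(values - mean) / sd).sum(axis=1)
    winner = int(np.argmin(scores))  # argmin keeps the first minimum: row order
    return str(df.index[winner])
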