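"""Synthetic two-class image cohorts with known ground-truth deformations.

The phantom plays the role of a real MRI cohort: a textured reference
"head", control subjects that are the reference under a small global
affine jitter plus a smooth random deformation plus noise, and diseased
subjects that additionally carry localized displacement lesions at known
loci.  Every subject ships with its exact ground-truth deformation field,
so registration, feature extraction and biomarker localization can all be
validated without external data.

The phantom reproduces only the statistical structure the pipeline
assumes — shared topology, smooth inter-subject deformation, a localized
disease effect — not anatomically realistic neuroanatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DeformationField, GrayImage

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "PhantomCohort",
    "make_reference",
    "make_subject",
    "generate_cohort",
    "write_cohort",
]

CONTROL = "control"
DISEASED = "diseased"


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe the standard validation cohort: 30 subjects split
    15/15, 128x128 pixels, one displacement lesion of peak amplitude 3 px
    and radius 8 px, smooth inter-subject background deformation of peak
    1 px (one third of the lesion amplitude, so the planted ground truth
    is detectable) with 12 px correlation length, a +-2 degree / +-2 px
    global setup jitter and 1% additive intensity noise.
    """

    image_size: int = 128
    n_control: int = 15
    n_diseased: int = 15
    global_jitter: tuple[float, float] = (2.0, 2.0)  # (max deg, max px)
    smooth_field_amplitude: float = 1.0  # peak magnitude, px
    smooth_field_scale: float = 12.0  # Gaussian correlation length, px
    lesion_centers: tuple[tuple[float, float], ...] | None = None
    lesion_amplitude: float = 3.0  # peak displacement, px
    lesion_radius: float = 8.0  # Gaussian sigma of the bump, px
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32 to contain the object")
        if self.n_control < 1 or self.n_diseased < 1:
            raise ValueError("both cohorts need at least one subject")
        for name in ("smooth_field_amplitude", "smooth_field_scale",
                     "lesion_amplitude", "lesion_radius", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(j < 0 for j in self.global_jitter):
            raise ValueError("global_jitter components must be >= 0")
        if self.lesion_centers is None:
            # default locus: inside the object, off-center
            s = self.image_size
            self.lesion_centers = ((0.42 * s, 0.58 * s),)
        self.lesion_centers = tuple(
            (float(r), float(c)) for r, c in self.lesion_centers
        )
        for r, c in self.lesion_centers:
            if not (0 <= r < self.image_size and 0 <= c < self.image_size):
                raise ValueError(f"lesion center ({r}, {c}) outside image bounds")


@dataclass
class PhantomSubject:
    image: GrayImage
    label: str
    ground_truth_field: DeformationField
    seed: int


@dataclass
class PhantomCohort:
    reference: GrayImage
    subjects: list[PhantomSubject]
    lesion_centers: tuple[tuple[float, float], ...]
    spec: PhantomSpec = dc_field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects])


def _subject_seed(master_seed: int, index: int) -> int:
    """Reproducible, mutually independent per-subject seed streams."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Zero-mean smooth random surface, normalized to unit max amplitude."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(raw).max()
    return raw / peak if peak > 0 else raw


def make_reference(spec: PhantomSpec) -> GrayImage:
    """Build the textured reference image.

    A head-like bounded object — nested ellipses with smooth intensity
    texture and gradients — on an exactly-zero background.  The texture
    carries intensity gradients over most of the object so that
    intensity-driven registration is well posed.  Deterministic for a
    fixed ``spec.seed``; intensities lie in [0, 1].
    """
    s = spec.image_size
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    rr, cc = np.mgrid[0:s, 0:s].astype(np.float64)
    cr = cm = s / 2.0

    # outer "cranium" ellipse
    a_r, a_c = 0.38 * s, 0.30 * s
    e_out = ((rr - cr) / a_r) ** 2 + ((cc - cm) / a_c) ** 2
    mask = e_out <= 1.0

    # inner "brain" ellipse, slightly offset
    a2_r, a2_c = 0.24 * s, 0.18 * s
    e_in = ((rr - cr + 0.04 * s) / a2_r) ** 2 + ((cc - cm - 0.02 * s) / a2_c) ** 2

    base = 0.55 + 0.20 * np.clip(1.0 - e_in, -1.0, 1.0)
    # radial shading toward the object boundary
    base -= 0.15 * np.clip(e_out, 0.0, 1.0)
    # two scales of smooth seeded texture for dense gradients
    base += 0.18 * _smooth_noise(rng, (s, s), s / 24.0)
    base += 0.10 * _smooth_noise(rng, (s, s), s / 48.0)

    img = np.zeros((s, s))
    inside = np.clip(base, 0.0, 1.0)
    # keep the object clearly above background
    inside = 0.15 + 0.85 * inside
    img[mask] = inside[mask]
    return GrayImage(img, subject_id="reference")


def _lesion_direction(spec: PhantomSpec, lesion_index: int) -> np.ndarray:
    """Fixed per-lesion displacement direction, derived from the cohort seed.

    All diseased subjects share the same lesion direction, emulating a
    consistent disease-driven deformation rather than per-subject noise.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 1_000_003 + lesion_index])
    )
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.sin(theta), np.cos(theta)])


def lesion_field(spec: PhantomSpec, shape: tuple[int, int]) -> np.ndarray:
    """Ground-truth lesion displacement: Gaussian-windowed bumps.

    Each lesion displaces pixels along a fixed unit direction with a
    radially symmetric Gaussian envelope: peak magnitude
    ``lesion_amplitude`` at the center, ~0 beyond 3 radii.
    """
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    u = np.zeros(shape + (2,))
    for i, (lr, lc) in enumerate(spec.lesion_centers):
        d = _lesion_direction(spec, i)
        r2 = (rr - lr) ** 2 + (cc - lc) ** 2
        env = spec.lesion_amplitude * np.exp(-r2 / (2.0 * spec.lesion_radius**2))
        u[..., 0] += env * d[0]
        u[..., 1] += env * d[1]
    return u


def make_subject(
    reference: GrayImage,
    label: str,
    spec: PhantomSpec,
    subject_seed: int,
) -> tuple[GrayImage, DeformationField]:
    """Warp the reference into one synthetic subject.

    The subject image is the reference resampled through the composed
    ground-truth map (global affine jitter applied after the smooth
    random field plus, for diseased subjects, the lesion field), with
    additive Gaussian intensity noise.  The returned field is the exact
    composed displacement on the reference grid (reference-pull
    convention), so ``warp_image(reference, field)`` reproduces the
    subject up to noise and interpolation.
    """
    if label not in (CONTROL, DISEASED):
        raise ValueError(f"label must be '{CONTROL}' or '{DISEASED}'")
    rng = np.random.default_rng(subject_seed)
    s = reference.shape[0]
    rr, cc = np.mgrid[0:reference.shape[0], 0:reference.shape[1]].astype(np.float64)

    # smooth random deformation, scaled to the requested peak magnitude
    u_sm = np.zeros(reference.shape + (2,))
    if spec.smooth_field_amplitude > 0:
        raw = np.stack(
            [
                ndimage.gaussian_filter(
                    rng.standard_normal(reference.shape), spec.smooth_field_scale
                )
                for _ in range(2)
            ],
            axis=-1,
        )
        peak = np.sqrt((raw**2).sum(axis=-1)).max()
        if peak > 0:
            u_sm = raw * (spec.smooth_field_amplitude / peak)
    else:
        rng.standard_normal(reference.shape)  # keep stream layout stable
        rng.standard_normal(reference.shape)

    u_local = u_sm
    if label == DISEASED and spec.lesion_amplitude > 0:
        u_local = u_sm + lesion_field(spec, reference.shape)

    # global affine jitter: rotation about center plus translation
    max_deg, max_px = spec.global_jitter
    theta = np.deg2rad(rng.uniform(-max_deg, max_deg))
    trans = rng.uniform(-max_px, max_px, size=2)
    ct, st = np.cos(theta), np.sin(theta)
    rot = np.array([[ct, -st], [st, ct]])
    center = np.array([(reference.shape[0] - 1) / 2.0,
                       (reference.shape[1] - 1) / 2.0])

    # composed sample location: affine applied to (x + u_local(x))
    p_r = rr + u_local[..., 0] - center[0]
    p_c = cc + u_local[..., 1] - center[1]
    s_r = rot[0, 0] * p_r + rot[0, 1] * p_c + center[0] + trans[0]
    s_c = rot[1, 0] * p_r + rot[1, 1] * p_c + center[1] + trans[1]
    u_total = np.stack([s_r - rr, s_c - cc], axis=-1)

    warped = ndimage.map_coordinates(
        reference.pixels, [s_r, s_c], order=1, mode="nearest"
    )
    if spec.noise_sd > 0:
        warped = warped + rng.normal(0.0, spec.noise_sd, size=warped.shape)
    warped = np.clip(warped, 0.0, 1.0)

    image = GrayImage(warped, reference.spacing)
    return image, DeformationField(u_total)


def generate_cohort(spec: PhantomSpec) -> PhantomCohort:
    """Generate the full two-class cohort, deterministically from the seed."""
    reference = make_reference(spec)
    subjects: list[PhantomSubject] = []
    labels = [CONTROL] * spec.n_control + [DISEASED] * spec.n_diseased
    for idx, label in enumerate(labels):
        seed = _subject_seed(spec.seed, idx)
        prefix = "ctrl" if label == CONTROL else "dis"
        sid = f"{prefix}{idx:03d}"
        image, gt = make_subject(reference, label, spec, seed)
        image.subject_id = sid
        subjects.append(PhantomSubject(image, label, gt, seed))
    return PhantomCohort(reference, subjects, spec.lesion_centers, spec)


def write_cohort(cohort: PhantomCohort, outdir: str | Path) -> Path:
    """Write a cohort to disk: 16-bit PNGs, ground-truth fields, manifest.

    Manifest schema (``manifest.csv``): one row per subject with columns
    ``subject_id, label, seed, image_path, field_path`` (paths relative to
    the cohort directory).  The reference image is ``reference.png`` and
    cohort-level metadata (spec, lesion centers) goes to ``cohort.json``.
    """
    outdir = Path(outdir)
    (outdir / "fields").mkdir(parents=True, exist_ok=True)

    def _save_png(img: GrayImage, path: Path) -> None:
        arr = np.clip(np.round(img.pixels * 65535.0), 0, 65535).astype(np.uint16)
        iio.imwrite(path, arr)

    _save_png(cohort.reference, outdir / "reference.png")
    rows = []
    for subj in cohort.subjects:
        sid = subj.image.subject_id
        img_rel = f"{sid}.png"
        fld_rel = f"fields/{sid}.npz"
        _save_png(subj.image, outdir / img_rel)
        subj.ground_truth_field.save(outdir / fld_rel)
        rows.append(
            {
                "subject_id": sid,
                "label": subj.label,
                "seed": subj.seed,
                "image_path": img_rel,
                "field_path": fld_rel,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    meta = {
        "reference_path": "reference.png",
        "lesion_centers": [list(c) for c in cohort.lesion_centers],
        "spec": asdict(cohort.spec) if cohort.spec is not None else None,
    }
    (outdir / "cohort.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return manifest
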