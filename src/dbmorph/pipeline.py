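"""End-to-end orchestration: preprocess → register → features → PCA →
SFFS → SVM/ROC → biomarker map.

Two evaluation modes are provided.  ``paper`` mode selects features once
on the whole cohort with SFFS and then cross-validates the SVM on those
fixed features — the reference protocol, but statistically optimistic
because the held-out subjects influenced the selection.  ``nested`` mode
re-runs feature selection inside every training split, which guards
against selection bias at extra cost (and with fewer SFFS orderings per
split by default).

Every stage's random seed is derived deterministically from the master
seed, so a full experiment is reproducible bit for bit from its config.
Deformation fields are cached in the output directory; re-running an
experiment reuses cached fields and reproduces identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .biomarkers import BiomarkerSet, localization_error, map_features_to_reference, render_overlay
from .classify import ROCCurve, SVMParams, leave_n_out_roc, plot_roc, train_svm, _as_binary, _round_tpr_on_grid
from .core import DeformationField, GrayImage
from .denoise import pca_denoise
from .features import FeatureMatrix, build_feature_matrix
from .image_prep import auto_crop_bbox, crop_and_normalize, load_image, load_manifest, select_reference
from .phantom import PhantomSpec, generate_cohort
from .registration import AffineParams, DemonsParams, register_affine, register_demons
from .sffs import FeatureScores, TopFeature, sffs_score, top_k

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "validate_config",
    "run_experiment",
    "nested_leave_n_out_roc",
]

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "rates": [3.0, 3.75, 5.0],
    "channels": ["magnitude", "direction"],
    "direction_encoding": "sincos",
    "pca_fraction": 0.95,
    "sffs_runs": 250,
    "top_k": 5,
    "cv_n_test": 5,
    "cv_rounds": 1000,
    "mode": "paper",
    "nested_sffs_runs": 25,
    "nested_cv_rounds": 100,
}

_STAGE_SEED_INDEX = {"phantom": 11, "sffs": 13, "cv": 17, "nested": 19}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_SEED_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    seed: int
    outdir: str = "dbmorph_out"
    phantom: dict[str, Any] | None = None
    manifest: str | None = None
    reference: str = "phantom"  # "phantom" | subject id | "table:<csv path>"
    affine: dict[str, Any] = dc_field(default_factory=dict)
    demons: dict[str, Any] = dc_field(default_factory=dict)
    rates: list[float] = dc_field(default_factory=lambda: list(DEFAULTS["rates"]))
    channels: list[str] = dc_field(
        default_factory=lambda: list(DEFAULTS["channels"])
    )
    direction_encoding: str = DEFAULTS["direction_encoding"]
    pca_fraction: float = DEFAULTS["pca_fraction"]
    sffs_runs: int = DEFAULTS["sffs_runs"]
    top_k: int = DEFAULTS["top_k"]
    svm: dict[str, Any] = dc_field(default_factory=dict)
    cv_n_test: int = DEFAULTS["cv_n_test"]
    cv_rounds: int = DEFAULTS["cv_rounds"]
    mode: str = DEFAULTS["mode"]
    nested_sffs_runs: int = DEFAULTS["nested_sffs_runs"]
    nested_cv_rounds: int = DEFAULTS["nested_cv_rounds"]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("outdir", None)  # where outputs go is not part of identity
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(source: str | Path | dict[str, Any]) -> ExperimentConfig:
    """Parse and validate a YAML/JSON config, reporting all problems at once.

    Defaults are the study's standard settings: rates [3, 3.75, 5], PCA
    fraction 0.95, 250 SFFS orderings, top-5 features, leave-5-out with
    1000 rounds.  The master ``seed`` is required.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config fields: {sorted(unknown)}")
    if "seed" not in raw or raw.get("seed") is None:
        errors.append("missing required field: seed")

    merged = {k: v for k, v in raw.items() if k in known}
    cfg = ExperimentConfig(seed=int(merged.pop("seed", 0)), **merged)

    if not (0 < cfg.pca_fraction <= 1):
        errors.append(f"pca_fraction must be in (0, 1], got {cfg.pca_fraction}")
    if any(r < 1 for r in cfg.rates) or not cfg.rates:
        errors.append(f"rates must be >= 1 and non-empty, got {cfg.rates}")
    if cfg.top_k < 1:
        errors.append(f"top_k must be >= 1, got {cfg.top_k}")
    if cfg.sffs_runs < 1:
        errors.append(f"sffs_runs must be >= 1, got {cfg.sffs_runs}")
    if cfg.cv_n_test < 1:
        errors.append(f"cv_n_test must be >= 1, got {cfg.cv_n_test}")
    if cfg.cv_rounds < 1:
        errors.append(f"cv_rounds must be >= 1, got {cfg.cv_rounds}")
    if cfg.mode not in ("paper", "nested"):
        errors.append(f"mode must be 'paper' or 'nested', got {cfg.mode!r}")
    if cfg.direction_encoding not in ("sincos", "angle"):
        errors.append(
            f"direction_encoding must be 'sincos' or 'angle', got "
            f"{cfg.direction_encoding!r}"
        )
    if cfg.phantom is None and cfg.manifest is None:
        errors.append("either a phantom spec or an input manifest is required")
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return cfg


@dataclass
class RateResult:
    rate: float
    scores: FeatureScores
    top_features: list[TopFeature]
    roc: ROCCurve
    biomarkers: BiomarkerSet
    localization_px: np.ndarray | None
    n_retained_components: int


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    per_rate: dict[float, RateResult]
    provenance: dict[str, Any]

    def summary(self) -> dict[str, Any]:
        rates = {}
        for rate, res in self.per_rate.items():
            rates[f"{rate:g}"] = {
                "auc": res.roc.auc,
                "n_cv_rounds": res.roc.n_rounds,
                "n_retained_components": res.n_retained_components,
                "top_features": [
                    {
                        "column": tf.column,
                        "score": tf.score,
                        "feature": tf.descriptor.name if tf.descriptor else None,
                    }
                    for tf in res.top_features
                ],
                "localization_px": (
                    [round(float(v), 6) for v in res.localization_px]
                    if res.localization_px is not None
                    else None
                ),
            }
        return {
            "config_hash": self.config.config_hash(),
            "mode": self.config.mode,
            "seed": self.config.seed,
            "rates": rates,
        }


class StageError(RuntimeError):
    """An error annotated with the pipeline stage (and subject) it hit."""


def _stage(name: str, subject: str | None = None):
    import contextlib

    @contextlib.contextmanager
    def ctx():
        try:
            yield
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and propagate
            where = f"stage '{name}'" + (f", subject '{subject}'" if subject else "")
            raise StageError(f"{where}: {exc}") from exc

    return ctx()


def _acquire_cohort(cfg: ExperimentConfig):
    """Returns (reference GrayImage, images list, labels list, lesion_centers|None)."""
    if cfg.phantom is not None:
        spec_kwargs = dict(cfg.phantom)
        spec_kwargs.setdefault("seed", stage_seed(cfg.seed, "phantom"))
        if "lesion_centers" in spec_kwargs and spec_kwargs["lesion_centers"]:
            spec_kwargs["lesion_centers"] = tuple(
                tuple(c) for c in spec_kwargs["lesion_centers"]
            )
        spec = PhantomSpec(**spec_kwargs)
        cohort = generate_cohort(spec)
        images = [s.image for s in cohort.subjects]
        labels = [s.label for s in cohort.subjects]
        lesions = cohort.lesion_centers if spec.lesion_amplitude > 0 else None
        return cohort.reference, images, labels, lesions
    manifest = load_manifest(cfg.manifest)
    base = Path(cfg.manifest).parent
    images, labels = [], []
    for _, row in manifest.iterrows():
        img = load_image(base / row["image_path"])
        img.subject_id = str(row["subject_id"])
        images.append(img)
        labels.append(str(row["label"]))
    if cfg.reference.startswith("table:"):
        table_path = cfg.reference.split(":", 1)[1]
        import pandas as pd

        ref_id = select_reference(pd.read_csv(table_path))
    elif cfg.reference == "phantom":
        raise ValueError("reference mode 'phantom' requires a phantom spec")
    else:
        ref_id = cfg.reference
    by_id = {img.subject_id: img for img in images}
    if ref_id not in by_id:
        raise ValueError(f"reference subject {ref_id!r} not in manifest")
    return by_id[ref_id].copy(), images, labels, None


def _register_all(
    cfg: ExperimentConfig,
    reference: GrayImage,
    images: list[GrayImage],
    fields_dir: Path,
    timings: dict[str, float],
) -> list[DeformationField]:
    affine_params = AffineParams(**cfg.affine)
    demons_params = DemonsParams(**cfg.demons)
    fields_dir.mkdir(parents=True, exist_ok=True)
    fields = []
    for img in images:
        sid = img.subject_id or "unknown"
        cache = fields_dir / f"{sid}.npz"
        if cache.exists():
            fields.append(DeformationField.load(cache))
            logger.info("registration: loaded cached field for %s", sid)
            continue
        t0 = time.perf_counter()
        with _stage("affine_registration", sid):
            _, aligned = register_affine(img, reference, affine_params)
        with _stage("demons_registration", sid):
            field = register_demons(aligned, reference, demons_params)
        field.save(cache)
        fields.append(field)
        logger.info(
            "registration: %s ssd %.4g -> %.4g (%.2fs)%s",
            sid, field.meta.get("ssd_initial"), field.meta.get("ssd_final"),
            time.perf_counter() - t0,
            " [diverged]" if field.meta.get("diverged") else "",
        )
    timings["registration"] = timings.get("registration", 0.0)
    return fields


def nested_leave_n_out_roc(
    X: FeatureMatrix,
    n_test: int = 5,
    n_rounds: int = 100,
    sffs_runs: int = 25,
    k: int = 5,
    seed: int = 0,
    svm_params: SVMParams | None = None,
) -> ROCCurve:
    """Leakage-free protocol: SFFS re-selected inside each training split.

    Within each round the feature scoring, top-k selection, and SVM
    standardization all see training subjects only; the held-out subjects
    are scored on the features the round selected.
    """
    yb, _ = _as_binary(X.labels)
    n = len(yb)
    if n_test >= n:
        raise ValueError("n_test must be smaller than the number of subjects")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    n_rejected = 0
    n_skipped = 0
    for rnd in range(n_rounds):
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
        run_seed = int(rng.integers(0, 2**31))
        scores = sffs_score(
            X.values[train_mask], yb[train_mask], n_runs=sffs_runs, seed=run_seed
        )
        cols = [tf.column for tf in top_k(scores, k=min(k, X.n_features))]
        model = train_svm(X.values[train_mask][:, cols], yb[train_mask], svm_params)
        held = model.decision_function(X.values[test_idx][:, cols])
        tprs.append(_round_tpr_on_grid(held, yb[test_idx], grid))
    if not tprs:
        raise RuntimeError("no cross-validation round had both classes in its test set")
    arr = np.vstack(tprs)
    return ROCCurve(grid, arr.mean(axis=0), arr.var(axis=0),
                    float(np.trapezoid(arr.mean(axis=0), grid)),
                    len(tprs), n_rejected, n_skipped)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full pipeline for every configured downsampling rate."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    failure_marker = outdir / "FAILED.json"

    try:
        t0 = time.perf_counter()
        with _stage("cohort"):
            reference, images, labels, lesions = _acquire_cohort(config)
        timings["cohort"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        with _stage("preprocess"):
            bbox = auto_crop_bbox(reference)
            ref_prep = crop_and_normalize(reference, bbox)
            imgs_prep = [crop_and_normalize(img, bbox) for img in images]
        timings["preprocess"] = time.perf_counter() - t0
        if lesions is not None:
            lesions = [(r - bbox[0], c - bbox[1]) for r, c in lesions]

        t0 = time.perf_counter()
        fields = _register_all(config, ref_prep, imgs_prep, outdir / "fields",
                               timings)
        timings["registration"] = time.perf_counter() - t0

        svm_params = SVMParams(**config.svm)
        per_rate: dict[float, RateResult] = {}
        for rate in config.rates:
            t0 = time.perf_counter()
            with _stage(f"features_rate_{rate:g}"):
                mats = build_feature_matrix(
                    fields, labels, [rate], config.channels,
                    config.direction_encoding,
                )
                mat = mats[rate]
            with _stage(f"pca_rate_{rate:g}"):
                pca = pca_denoise(mat, config.pca_fraction)
                denoised = pca.reconstructed
                logger.info("rate %g: retained %d/%d components", rate,
                            pca.n_retained, len(pca.explained_fraction))

            if config.mode == "paper":
                with _stage(f"sffs_rate_{rate:g}"):
                    scores = sffs_score(
                        denoised, n_runs=config.sffs_runs,
                        seed=stage_seed(config.seed, "sffs"),
                    )
                    tops = top_k(scores, k=min(config.top_k, denoised.n_features))
                with _stage(f"cv_rate_{rate:g}"):
                    cols = [tf.column for tf in tops]
                    roc = leave_n_out_roc(
                        denoised.values[:, cols], denoised.labels,
                        n_test=config.cv_n_test, n_rounds=config.cv_rounds,
                        seed=stage_seed(config.seed, "cv"), params=svm_params,
                    )
            else:
                with _stage(f"sffs_rate_{rate:g}"):
                    scores = sffs_score(
                        denoised, n_runs=config.sffs_runs,
                        seed=stage_seed(config.seed, "sffs"),
                    )
                    tops = top_k(scores, k=min(config.top_k, denoised.n_features))
                with _stage(f"nested_cv_rate_{rate:g}"):
                    roc = nested_leave_n_out_roc(
                        denoised, n_test=config.cv_n_test,
                        n_rounds=config.nested_cv_rounds,
                        sffs_runs=config.nested_sffs_runs, k=config.top_k,
                        seed=stage_seed(config.seed, "nested"),
                        svm_params=svm_params,
                    )

            with _stage(f"biomarkers_rate_{rate:g}"):
                bset = map_features_to_reference(
                    [tf.descriptor for tf in tops], ref_prep.shape,
                    [tf.score for tf in tops],
                )
                loc = (np.asarray(localization_error(bset, lesions))
                       if lesions else None)

            tag = f"rate{rate:g}".replace(".", "p")
            scores.to_csv(outdir / f"scores_{tag}.csv")
            mat.to_csv(outdir / f"features_{tag}.csv")
            roc.to_csv(outdir / f"roc_{tag}.csv")
            roc.save_summary(outdir / f"roc_{tag}.json", {"rate": rate})
            bset.to_csv(outdir / f"biomarkers_{tag}.csv")
            bset.to_json(outdir / f"biomarkers_{tag}.json")
            render_overlay(ref_prep, [bset], outdir / f"overlay_{tag}.png")
            timings[f"rate_{rate:g}"] = time.perf_counter() - t0
            per_rate[rate] = RateResult(rate, scores, tops, roc, bset, loc,
                                        pca.n_retained)

        plot_roc(
            {f"{r:g}x{r:g}": res.roc for r, res in per_rate.items()},
            outdir / "roc_curves.png",
        )

        import scipy
        import sklearn

        provenance = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "mode": config.mode,
            "stage_seeds": {s: stage_seed(config.seed, s) for s in
                            _STAGE_SEED_INDEX},
            "versions": {
                "dbmorph": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }
        report = ExperimentReport(config, per_rate, provenance)
        (outdir / "report.json").write_text(
            json.dumps(report.summary(), indent=2, sort_keys=True)
        )
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True)
        )
        # timings are informational and deliberately not part of report.json,
        # which is byte-reproducible for a fixed config
        (outdir / "timings.json").write_text(
            json.dumps({k: round(v, 3) for k, v in timings.items()},
                       indent=2, sort_keys=True)
        )
        if failure_marker.exists():
            failure_marker.unlink()
        return report
    except Exception as exc:
        failure_marker.write_text(
            json.dumps({"error": str(exc)}, indent=2)
        )
        raise
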