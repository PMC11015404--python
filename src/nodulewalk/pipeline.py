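"""End-to-end orchestration: phantoms -> denoise -> segment -> features ->
classify -> metrics.

The four processing stages run in a fixed order per sample:

1. Perona-Malik anisotropic diffusion on the raw slice;
2. LBP coding of the denoised slice (RWI only);
3. seeded random-walker segmentation (seeds derived from the ground-truth
   mask for phantom runs, or supplied as a CSV for file inputs) plus
   morphological post-processing;
4. feature extraction on the denoised slice restricted to the predicted
   mask.

Classification is stratified k-fold cross-validation over the resulting
feature table; the pooled confusion counts feed the metric suite.
Samples whose segmentation comes back empty are skipped and logged, never
aborted on.  A config plus seed fixes every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .classify import LabeledDataset, cross_validate
from .errors import InvalidParamsError
from .features import FEATURE_NAMES, extract_features
from .phantom import PhantomSample, SpecRanges, generate_dataset
from .preprocess import DiffusionParams, anisotropic_diffusion
from .rw_segment import RWParams, auto_seeds, segment
from .texture_lbp import lbp_map

logger = logging.getLogger("nodulewalk")


@dataclass
class PipelineConfig:
    """Every stage parameter, with defaults that run the phantom demo.

    method : weight scheme for segmentation, "rw" or "rwi".
    classifier : "rf" or "ann".
    """

    n_samples: int = 200
    malignant_fraction: float = 0.5
    rng_seed: int = 7
    image_size: tuple[int, int] = (128, 128)
    spec_ranges: SpecRanges = field(default_factory=SpecRanges)
    method: str = "rwi"
    classifier: str = "rf"
    folds: int = 5
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    rw: RWParams = field(default_factory=RWParams)
    seed_margin: int = 12
    glcm_levels: int = 8
    glcm_distance: int = 1
    wavelet: str = "haar"
    intensity_on_subband: bool = True
    out_dir: str | None = None

    def validate(self) -> None:
        if self.method not in ("rw", "rwi"):
            raise InvalidParamsError(f"method must be 'rw' or 'rwi', got {self.method!r}")
        if self.classifier not in ("rf", "ann"):
            raise InvalidParamsError(
                f"classifier must be 'rf' or 'ann', got {self.classifier!r}"
            )
        self.diffusion.validate()
        self.rw.validate()

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self)
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "rng_seed": self.rng_seed,
            "feature_names": list(FEATURE_NAMES),
        }


@dataclass
class SegmentedSample:
    """One phantom with its denoised slice and predicted mask."""

    sample: PhantomSample
    denoised: np.ndarray
    mask_pred: np.ndarray
    dice: float


def segment_samples(
    samples, config: PipelineConfig, method: str | None = None
) -> tuple[list[SegmentedSample], list[int]]:
    """Stages 1-3 for a batch of phantoms; returns results and skipped ids."""
    method = method or config.method
    results: list[SegmentedSample] = []
    skipped: list[int] = []
    for i, s in enumerate(samples):
        denoised = anisotropic_diffusion(s.image, config.diffusion)
        codes = lbp_map(denoised) if method == "rwi" else None
        seeds = auto_seeds(s.mask, margin=config.seed_margin)
        _, seg = segment(denoised, seeds, config.rw, method=method,
                         lbp_codes=codes)
        if not seg.mask.any():
            logger.warning("sample %d: empty segmentation, skipped", i)
            skipped.append(i)
            continue
        results.append(SegmentedSample(
            sample=s,
            denoised=denoised,
            mask_pred=seg.mask,
            dice=metrics_mod.dice(seg.mask, s.mask),
        ))
    return results, skipped


def build_feature_table(segmented: list[SegmentedSample],
                        config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for item in segmented:
        vec = extract_features(
            item.denoised, item.mask_pred,
            glcm_levels=config.glcm_levels,
            glcm_distance=config.glcm_distance,
            wavelet=config.wavelet,
            intensity_on_subband=config.intensity_on_subband,
        )
        rows.append(vec)
    table = pd.DataFrame(rows).reset_index(drop=True)
    table["label"] = [item.sample.label for item in segmented]
    return table


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run the full study described by the config.

    Returns a dict with the feature table, per-sample Dice scores, the
    cross-validation result, the pooled :class:`MetricsReport`, skipped
    sample indices and a reproducibility manifest.  With ``out_dir`` set,
    also writes features.csv, metrics.json, manifest.json and the
    predicted masks as PNGs.
    """
    config = config if config is not None else PipelineConfig()
    config.validate()

    samples = generate_dataset(
        config.n_samples,
        malignant_fraction=config.malignant_fraction,
        spec_ranges=config.spec_ranges,
        rng_seed=config.rng_seed,
        image_size=config.image_size,
    )
    segmented, skipped = segment_samples(samples, config)
    table = build_feature_table(segmented, config)
    data = LabeledDataset.from_table(table)
    cv = cross_validate(data, kind=config.classifier, k=config.folds,
                        rng_seed=config.rng_seed)
    report = metrics_mod.compute_metrics(cv.pooled)

    result = {
        "features": table,
        "dice": np.array([item.dice for item in segmented]),
        "cv": cv,
        "metrics": report,
        "skipped": skipped,
        "manifest": config.manifest(),
        "segmented": segmented,
    }
    if config.out_dir:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: dict, config: PipelineConfig) -> None:
    import imageio.v3 as iio

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["features"].to_csv(out / "features.csv", index=False)
    (out / "metrics.json").write_text(result["metrics"].to_json(indent=2))
    (out / "manifest.json").write_text(
        json.dumps(result["manifest"], indent=2, default=str)
    )
    masks_dir = out / "masks"
    masks_dir.mkdir(exist_ok=True)
    for i, item in enumerate(result["segmented"]):
        iio.imwrite(masks_dir / f"mask_{i:04d}.png",
                    item.mask_pred.astype(np.uint8) * 255)


METRIC_ROWS = (
    "accuracy", "f1", "error", "fpr", "sensitivity", "mcc", "kappa",
    "precision", "specificity",
)


def evaluate_methods(config: PipelineConfig | None = None) -> dict:
    """Paired comparison grid: {rw, rwi} x {rf, ann} on one shared dataset.

    All four cells segment and classify the *same* phantoms with the same
    seeds, so differences are attributable to the method.  Returns the
    metric grid (rows = metric names, columns = method_classifier), the
    per-method mean Dice, and the paired per-sample Dice arrays.
    """
    config = config if config is not None else PipelineConfig()
    config.validate()
    samples = generate_dataset(
        config.n_samples,
        malignant_fraction=config.malignant_fraction,
        spec_ranges=config.spec_ranges,
        rng_seed=config.rng_seed,
        image_size=config.image_size,
    )

    grid: dict[str, dict[str, float]] = {}
    dice_by_method: dict[str, np.ndarray] = {}
    for method in ("rw", "rwi"):
        segmented, skipped = segment_samples(samples, config, method=method)
        if skipped:
            logger.warning("method %s skipped samples: %s", method, skipped)
        dice_by_method[method] = np.array([it.dice for it in segmented])
        table = build_feature_table(segmented, config)
        data = LabeledDataset.from_table(table)
        for clf in ("rf", "ann"):
            cv = cross_validate(data, kind=clf, k=config.folds,
                                rng_seed=config.rng_seed)
            report = metrics_mod.compute_metrics(cv.pooled).as_dict()
            grid[f"{method}_{clf}"] = {row: report[row] for row in METRIC_ROWS}

    grid_df = pd.DataFrame(grid).loc[list(METRIC_ROWS)]
    out = {
        "grid": grid_df,
        "mean_dice": {m: float(d.mean()) for m, d in dice_by_method.items()},
        "dice": dice_by_method,
    }
    if config.out_dir:
        outdir = Path(config.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        grid_df.to_csv(outdir / "method_comparison.csv")
    return out
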