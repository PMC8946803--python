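"""End-to-end orchestration: cohort on disk -> patch table -> features ->
leave-one-patient-out report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from hsi_oncopipe import annotation as ann
from hsi_oncopipe import preprocessing as pp
from hsi_oncopipe.bands import BandTable, make_band_table
from hsi_oncopipe.errors import ContractError
from hsi_oncopipe.evaluation import MetricsReport, lopo_cv
from hsi_oncopipe.features import default_feature_specs, feature_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline knobs; serialized into every output report."""

    band_centers_nm: list[float] | None = None
    glare_threshold: float = pp.DEFAULT_GLARE_THRESHOLD
    background_threshold: float = pp.DEFAULT_BACKGROUND_THRESHOLD
    edge_margin: int = pp.DEFAULT_EDGE_MARGIN
    block_size: int = pp.DEFAULT_BLOCK_SIZE
    min_valid_fraction: float = pp.DEFAULT_MIN_VALID_FRACTION
    feature_mode: str = "hybrid"
    normalize_before_patching: bool = False
    svm_C: float = 1.0
    threshold_mode: str = "test_youden"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def bands(self) -> BandTable:
        return make_band_table(self.band_centers_nm)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {k: v for k, v in payload.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class StageCounts:
    """Pixel/patch bookkeeping for one sample, logged per stage."""

    sample: str
    pixels: int = 0
    background: int = 0
    glare: int = 0
    edge: int = 0
    invalid_reference: int = 0
    valid: int = 0
    patches_total: int = 0
    patches_excluded: int = 0
    patches_retained: int = 0


def process_sample(
    raw_frame: np.ndarray,
    white_frame: np.ndarray,
    dark_frame: np.ndarray,
    annotation_labels: np.ndarray,
    config: PipelineConfig,
    patient_id: str = "",
    sample_id: str = "",
) -> tuple[pd.DataFrame, StageCounts]:
    """Run one sample through demosaic -> calibrate -> masking -> patching.

    ``annotation_labels`` must already be registered into demosaiced
    hyperspectral coordinates.  Edge erosion is computed from the
    background/invalid-reference mask only, then glare exclusion is
    overlaid: a stray saturated pixel costs itself, not a 20-pixel halo,
    while tissue-background borders lose the full margin.
    """
    bands = config.bands
    cube = pp.calibrate(
        pp.demosaic(raw_frame, bands),
        pp.ReferenceSet(
            pp.demosaic(white_frame, bands).data.astype(float),
            pp.demosaic(dark_frame, bands).data.astype(float),
        ),
    )
    full_mask = pp.make_validity_mask(
        cube, config.glare_threshold, config.background_threshold
    )
    # erosion driven by tissue/background geometry, not isolated glare
    bg_reasons = full_mask.reasons.copy()
    bg_reasons[bg_reasons == pp.Reason.GLARE] = pp.Reason.VALID
    eroded = pp.erode_edges(pp.ValidityMask(bg_reasons), config.edge_margin)
    reasons = eroded.reasons.copy()
    glare = full_mask.reasons == pp.Reason.GLARE
    reasons[glare & (reasons == pp.Reason.VALID)] = pp.Reason.GLARE
    mask = pp.ValidityMask(reasons)

    cube_for_patches = cube
    if config.normalize_before_patching:
        cube_for_patches = pp.Hypercube(
            pp.minmax_normalize(cube.data), bands, stage="normalized",
            invalid_reference=cube.invalid_reference,
        )
    patches = pp.patch_average(
        cube_for_patches,
        mask,
        annotation_labels,
        block=config.block_size,
        min_valid_fraction=config.min_valid_fraction,
        patient_id=patient_id,
        sample_id=sample_id,
    )
    c = mask.counts()
    retained = int((patches["label"] != "excluded").sum()) if len(patches) else 0
    counts = StageCounts(
        sample=f"{patient_id}/{sample_id}",
        pixels=int(np.prod(cube.shape[:2])),
        background=c["background"],
        glare=c["glare"],
        edge=c["edge"],
        invalid_reference=c["invalid_reference"],
        valid=c["valid"],
        patches_total=len(patches),
        patches_excluded=len(patches) - retained,
        patches_retained=retained,
    )
    logger.info("sample %s: %s", counts.sample, counts)
    return patches, counts


def load_and_register_annotation(
    annotation_png, control_points_csv, output_shape: tuple[int, int],
    hsv_windows=None,
) -> np.ndarray:
    """HSV-threshold an annotation overlay and warp it into cube coordinates."""
    rgb = np.asarray(iio.imread(annotation_png))[:, :, :3].astype(np.uint8)
    labels = ann.hsv_masks(rgb, hsv_windows)
    points = ann.ControlPointSet.from_csv(control_points_csv)
    return ann.tps_warp(labels, points, order=0, output_shape=output_shape)


def simulate_patch_features(
    n_patients: int,
    samples_per_patient: int,
    cohort_config=None,
    pipeline_config: PipelineConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Render a synthetic cohort in memory and preprocess it to a feature
    table, without touching disk.  Mirrors generate_cohort + run_pipeline
    up to (and excluding) cross-validation; annotation labels go through
    the HSV-thresholding path.
    """
    from hsi_oncopipe.synthetic import CohortConfig, make_default_library, make_scene, render_sample

    cohort_config = cohort_config or CohortConfig()
    config = pipeline_config or PipelineConfig()
    bands = config.bands
    library = make_default_library(
        bands,
        separation=cohort_config.separation,
        amplitude_sd=cohort_config.amplitude_sd,
        noise_sd=cohort_config.noise_sd,
    )
    rng = np.random.default_rng(seed)
    tables = []
    for p in range(n_patients):
        prevalence = cohort_config.prevalence_for(p)
        for s in range(samples_per_patient):
            scene = make_scene(cohort_config, prevalence, int(rng.integers(2**31)), rng)
            rendered = render_sample(scene, library, bands)
            labels = ann.hsv_masks(rendered.annotation_rgb)
            patches, _ = process_sample(
                rendered.raw, rendered.white, rendered.dark, labels, config,
                patient_id=f"P{p + 1:02d}", sample_id=f"S{s + 1}",
            )
            tables.append(patches)
    all_patches = pd.concat(tables, ignore_index=True)
    return feature_table(
        all_patches, bands, default_feature_specs(), mode=config.feature_mode
    )


def run_pipeline(
    cohort_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    keep_going: bool = False,
) -> MetricsReport:
    """Execute the full analysis over a cohort directory with a manifest.

    Writes ``patches.csv``, ``features.csv``, ``report.csv``,
    ``report.json`` and a config snapshot when ``out_dir`` is given.
    """
    config = config or PipelineConfig()
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.csv"
    if not manifest_path.exists():
        raise ContractError(f"no manifest.csv under {cohort_dir}")
    manifest = pd.read_csv(manifest_path)
    bands = config.bands
    tables, stage_counts = [], []
    for _, row in manifest.iterrows():
        try:
            raw = tifffile.imread(cohort_dir / row["raw_path"]).astype(float)
            white = tifffile.imread(cohort_dir / row["white_path"]).astype(float)
            dark = tifffile.imread(cohort_dir / row["dark_path"]).astype(float)
            shape = (raw.shape[0] // 5, raw.shape[1] // 5)
            labels = load_and_register_annotation(
                cohort_dir / row["annotation_path"],
                cohort_dir / row["control_points_path"],
                shape,
            )
            patches, counts = process_sample(
                raw, white, dark, labels, config,
                patient_id=str(row["patient_id"]), sample_id=str(row["sample_id"]),
            )
            tables.append(patches)
            stage_counts.append(counts)
        except Exception as exc:
            msg = f"sample {row['patient_id']}/{row['sample_id']}: {exc}"
            if not keep_going:
                raise RuntimeError(msg) from exc
            logger.error("skipping %s", msg)
    all_patches = pd.concat(tables, ignore_index=True)
    features = feature_table(all_patches, bands, default_feature_specs(), mode=config.feature_mode)
    report = lopo_cv(features, C=config.svm_C, threshold_mode=config.threshold_mode)
    report.config = {**report.config, **asdict(config)}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        all_patches.to_csv(out_dir / "patches.csv", index=False)
        features.to_csv(out_dir / "features.csv", index=False)
        report.to_csv(out_dir / "report.csv")
        report.to_json(out_dir / "report.json")
        config.to_yaml(out_dir / "config.yaml")
        with open(out_dir / "stage_counts.json", "w") as fh:
            json.dump([asdict(c) for c in stage_counts], fh, indent=2)
    return report
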