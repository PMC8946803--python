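"""Synthetic cohort generator emulating the snapshot-mosaic camera and the
histopathology ground truth.

A rendered sample consists of a raw 5x5-mosaic frame, white and dark
reference frames, an RGB annotation overlay (bordeaux = tumor,
blue = non-tumor, green = mixed, white = background) and a per-pixel
ground-truth label mask.  Per-class reflectance shapes are smooth
synthetic curves; per-pixel spectra of one class differ only by a
log-normal amplitude factor, so they run in parallel across bands and
band ratios carry the class signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from pathlib import Path
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon2mask

from hsi_oncopipe.bands import MOSAIC_SIZE, N_BANDS, BandTable, make_band_table
from hsi_oncopipe.errors import ConfigurationError, ContractError
from hsi_oncopipe.preprocessing import (
    LABEL_MIXED,
    LABEL_NON_TUMOR,
    LABEL_TUMOR,
    LABEL_UNANNOTATED,
)

ANNOTATION_COLORS = {
    LABEL_TUMOR: (128, 0, 32),      # bordeaux
    LABEL_NON_TUMOR: (0, 0, 255),   # blue
    LABEL_MIXED: (0, 200, 0),       # green marker
    LABEL_UNANNOTATED: (255, 255, 255),
}


@dataclass(frozen=True)
class SpectralLibrary:
    """Per-class reflectance endmembers plus spread parameters.

    ``amplitude_sd`` is the log-scale sigma of the single multiplicative
    amplitude draw applied to each spectrum; ``noise_sd`` is additive
    per-band Gaussian noise.
    """

    endmembers: dict[str, np.ndarray]
    amplitude_sd: float = 0.15
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        fixed = {}
        for name, vec in self.endmembers.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (N_BANDS,):
                raise ConfigurationError(
                    f"endmember {name!r} must have length {N_BANDS}"
                )
            if arr.min() < 0 or arr.max() > 1:
                raise ConfigurationError(f"endmember {name!r} outside [0, 1]")
            fixed[name] = arr
        object.__setattr__(self, "endmembers", fixed)

    def __contains__(self, name: str) -> bool:
        return name in self.endmembers


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def make_default_library(
    bands: BandTable | None = None,
    separation: float = 1.0,
    amplitude_sd: float = 0.10,
    noise_sd: float = 0.0,
) -> SpectralLibrary:
    """Smooth synthetic endmembers (linear continuum + Gaussian bumps).

    ``separation`` scales the spectral-shape difference between the tumor
    class and the connective base shape: 0 makes them identical, larger
    values pull them apart.
    """
    bands = bands or make_band_table()
    t = (bands.centers - 665.0) / 310.0
    connective = 0.30 + 0.18 * t + 0.10 * _bump(t, 0.35, 0.12) + 0.06 * _bump(t, 0.80, 0.10)
    stroma = 0.26 + 0.14 * t + 0.13 * _bump(t, 0.55, 0.15) + 0.05 * _bump(t, 0.15, 0.10)
    fat = 0.38 + 0.08 * t + 0.12 * _bump(t, 0.25, 0.08) + 0.08 * _bump(t, 0.70, 0.12)
    delta = 0.10 * _bump(t, 0.15, 0.10) - 0.09 * _bump(t, 0.50, 0.12) + 0.10 * _bump(t, 0.90, 0.08)
    tumor = np.clip(connective + separation * delta, 0.02, 0.90)
    members = {
        "tumor": tumor,
        "connective": np.clip(connective, 0.0, 0.90),
        "stroma": np.clip(stroma, 0.0, 0.90),
        "fat": np.clip(fat, 0.0, 0.90),
    }
    return SpectralLibrary(members, amplitude_sd=amplitude_sd, noise_sd=noise_sd)


def sample_spectrum(
    library: SpectralLibrary,
    class_name: str,
    tumor_fraction: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw one pixel spectrum: convex endmember mixture x log-normal
    amplitude + per-band Gaussian noise, clipped to [0, 1].
    """
    if class_name not in library:
        raise KeyError(f"unknown tissue class {class_name!r}")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ContractError("tumor_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    mix = (
        tumor_fraction * library.endmembers["tumor"]
        + (1.0 - tumor_fraction) * library.endmembers[class_name]
    )
    amplitude = np.exp(rng.normal(0.0, library.amplitude_sd)) if library.amplitude_sd else 1.0
    noise = rng.normal(0.0, library.noise_sd, N_BANDS) if library.noise_sd else 0.0
    return np.clip(mix * amplitude + noise, 0.0, 1.0)


@dataclass(frozen=True)
class Region:
    """Polygonal scene region: vertices are (row, col) pixel coordinates."""

    polygon: np.ndarray  # n x 2
    class_name: str
    tumor_fraction: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "polygon", np.asarray(self.polygon, dtype=float))
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ConfigurationError("tumor_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SceneSpec:
    """Fully deterministic description of one rendered sample."""

    rows: int
    cols: int
    regions: tuple[Region, ...]
    seed: int
    glare_fraction: float = 0.0
    illumination_amplitude: float = 0.2  # 0 = uniform field
    illumination_smoothness: float = 30.0
    dark_current_level: float = 100.0
    white_level: float = 3000.0
    saturation_value: float = 4095.0
    background_reflectance: float = 0.02
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.glare_fraction <= 1.0:
            raise ConfigurationError("glare_fraction must lie in [0, 1]")


@dataclass
class RenderedSample:
    """In-memory result of rendering one scene."""

    raw: np.ndarray          # mosaic frame (5*rows x 5*cols)
    white: np.ndarray        # mosaic white reference
    dark: np.ndarray         # mosaic dark reference
    annotation_rgb: np.ndarray  # rows x cols x 3 uint8
    truth: np.ndarray        # rows x cols label mask
    reflectance: np.ndarray  # rows x cols x 25 ground-truth reflectance


def _rasterize(scene: SceneSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (class index, tumor fraction, truth label) maps."""
    shape = (scene.rows, scene.cols)
    class_idx = np.full(shape, -1, dtype=int)
    fraction = np.zeros(shape)
    truth = np.full(shape, LABEL_UNANNOTATED, dtype=np.uint8)
    for k, region in enumerate(scene.regions):
        m = polygon2mask(shape, region.polygon)
        if np.any(m & (class_idx >= 0)):
            raise ConfigurationError("scene regions overlap")
        class_idx[m] = k
        fraction[m] = region.tumor_fraction
        if region.tumor_fraction > 0.5:
            truth[m] = LABEL_TUMOR
        elif region.tumor_fraction > 0.0:
            truth[m] = LABEL_MIXED
        else:
            truth[m] = LABEL_NON_TUMOR
    return class_idx, fraction, truth


def _illumination_field(scene: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if scene.illumination_amplitude == 0:
        return np.ones((scene.rows, scene.cols))
    raw = rng.normal(size=(scene.rows, scene.cols))
    smooth = gaussian_filter(raw, sigma=scene.illumination_smoothness)
    lo, hi = smooth.min(), smooth.max()
    unit = (smooth - lo) / (hi - lo) if hi > lo else np.zeros_like(smooth)
    return 1.0 - scene.illumination_amplitude * unit


def render_sample(
    scene: SceneSpec, library: SpectralLibrary, bands: BandTable
) -> RenderedSample:
    """Render a scene to raw/white/dark mosaic frames plus annotations.

    raw = reflectance x illumination x white_level + dark current
    (+ optional read noise), written in 5x5 mosaic layout; glare pixels
    saturate all 25 mosaic positions; the background is black paper near
    reflectance 0.02.
    """
    rng = np.random.default_rng(scene.seed)
    rows, cols = scene.rows, scene.cols
    class_idx, fraction, truth = _rasterize(scene)

    refl = np.empty((rows, cols, N_BANDS))
    bg = scene.background_reflectance
    refl[:] = np.clip(
        bg * np.exp(rng.normal(0.0, 0.1, (rows, cols)))[:, :, None], 0.0, 1.0
    )
    for k, region in enumerate(scene.regions):
        sel = class_idx == k
        n = int(sel.sum())
        if n == 0:
            continue
        mix = (
            region.tumor_fraction * library.endmembers["tumor"]
            + (1.0 - region.tumor_fraction) * library.endmembers[region.class_name]
        )
        amp = (
            np.exp(rng.normal(0.0, library.amplitude_sd, (n, 1)))
            if library.amplitude_sd
            else np.ones((n, 1))
        )
        noise = rng.normal(0.0, library.noise_sd, (n, N_BANDS)) if library.noise_sd else 0.0
        refl[sel] = np.clip(mix[None, :] * amp + noise, 0.0, 1.0)

    illum = _illumination_field(scene, rng)
    glare = rng.random((rows, cols)) < scene.glare_fraction

    mosaic_shape = (rows * MOSAIC_SIZE, cols * MOSAIC_SIZE)
    raw = np.empty(mosaic_shape)
    white = np.empty(mosaic_shape)
    dark = np.full(mosaic_shape, scene.dark_current_level)
    for b, (r, c) in bands.mosaic_offsets.items():
        signal = refl[:, :, b] * illum * scene.white_level + scene.dark_current_level
        signal[glare] = scene.saturation_value
        raw[r::MOSAIC_SIZE, c::MOSAIC_SIZE] = signal
        white[r::MOSAIC_SIZE, c::MOSAIC_SIZE] = illum * scene.white_level + scene.dark_current_level
    if scene.read_noise_sd:
        raw = raw + rng.normal(0.0, scene.read_noise_sd, mosaic_shape)
        white = white + rng.normal(0.0, scene.read_noise_sd, mosaic_shape)
        dark = dark + rng.normal(0.0, scene.read_noise_sd, mosaic_shape)

    annotation = np.empty((rows, cols, 3), dtype=np.uint8)
    for label, color in ANNOTATION_COLORS.items():
        annotation[truth == label] = color
    return RenderedSample(raw, white, dark, annotation, truth, refl)


@dataclass(frozen=True)
class CohortConfig:
    """Knobs for whole-cohort generation; every field has a sane default."""

    scene_rows: int = 220
    scene_cols: int = 220
    margin: int = 6  # background border around the tissue slab, pixels
    separation: float = 1.0
    amplitude_sd: float = 0.10
    noise_sd: float = 0.01
    glare_fraction: float = 0.005
    illumination_amplitude: float = 0.2
    read_noise_sd: float = 0.0
    regions_per_sample: int = 4
    mixed_probability: float = 0.1
    tumor_prevalence: float | tuple[float, ...] = 0.45
    non_tumor_classes: tuple[str, ...] = ("connective", "stroma", "fat")
    organs: tuple[str, ...] = ("ovarian", "omentum", "intestines", "mesenterium")
    n_control_points: int = 20
    region_align: int = 20  # snap strip borders to the patch grid; 0 disables

    def prevalence_for(self, patient_index: int) -> float:
        if isinstance(self.tumor_prevalence, (int, float)):
            return float(self.tumor_prevalence)
        return float(self.tumor_prevalence[patient_index % len(self.tumor_prevalence)])


def make_scene(
    config: CohortConfig, prevalence: float, seed: int, rng: np.random.Generator
) -> SceneSpec:
    """One tissue slab split into vertical strip regions.

    Each strip draws a non-tumor class; with probability ``prevalence``
    it becomes tumor (cell fraction 0.6-1.0), and with
    ``mixed_probability`` a low-content mixed region (fraction 0.05-0.5)
    that ground truth excludes.
    """
    rows, cols, m = config.scene_rows, config.scene_cols, config.margin
    n = config.regions_per_sample
    edges = np.linspace(m, cols - m, n + 1).astype(int)
    if config.region_align > 1:
        # snap interior strip borders onto the patch grid so class regions
        # can contain whole pure blocks
        a = config.region_align
        inner = np.round(edges[1:-1] / a).astype(int) * a
        edges = np.concatenate([[edges[0]], np.clip(inner, m + 1, cols - m - 1), [edges[-1]]])
        edges = np.maximum.accumulate(edges)
    regions = []
    eps = 1e-3
    r0, r1 = m - 0.5 + eps, rows - m - 0.5 - eps
    for i in range(n):
        # strip i covers pixel columns [edges[i], edges[i+1]) exactly:
        # polygon bounds at half-integers keep adjacent strips disjoint
        c0, c1 = edges[i] - 0.5 + eps, edges[i + 1] - 0.5 - eps
        poly = [(r0, c0), (r0, c1), (r1, c1), (r1, c0)]
        u = rng.random()
        if u < prevalence:
            cls, frac = "connective", float(rng.uniform(0.6, 1.0))
        elif u < prevalence + config.mixed_probability:
            cls, frac = "connective", float(rng.uniform(0.05, 0.5))
        else:
            cls, frac = str(rng.choice(config.non_tumor_classes)), 0.0
        regions.append(Region(np.array(poly, dtype=float), cls, frac))
    return SceneSpec(
        rows=rows,
        cols=cols,
        regions=tuple(regions),
        seed=seed,
        glare_fraction=config.glare_fraction,
        illumination_amplitude=config.illumination_amplitude,
        read_noise_sd=config.read_noise_sd,
    )


def _control_points(scene: SceneSpec, n: int) -> pd.DataFrame:
    """Identity control-point pairs on a grid covering the frame."""
    side = max(2, int(np.ceil(np.sqrt(n))))
    ys = np.linspace(0, scene.rows - 1, side)
    xs = np.linspace(0, scene.cols - 1, side)
    pts = [(y, x) for y in ys for x in xs][:max(n, 4)]
    arr = np.array(pts)
    return pd.DataFrame(
        {"x_src": arr[:, 1], "y_src": arr[:, 0], "x_dst": arr[:, 1], "y_dst": arr[:, 0]}
    )


def generate_cohort(
    out_dir: str | Path,
    n_patients: int = 10,
    samples_per_patient: int | tuple[int, ...] = 2,
    config: CohortConfig | None = None,
    seed: int = 0,
    bands: BandTable | None = None,
) -> pd.DataFrame:
    """Write a full synthetic cohort to disk and return its manifest.

    Layout: ``<out>/P<k>/S<j>/{raw,white,dark}.tif`` (single-page TIFF),
    ``annotation.png``, ``truth.png``, ``control_points.csv``, plus a
    top-level ``manifest.csv`` and ``bands.csv``.  Identical
    (config, seed) produce byte-identical manifests and rasters.
    """
    if n_patients < 2:
        raise ContractError("need >= 2 patients for a meaningful cohort")
    config = config or CohortConfig()
    bands = bands or make_band_table()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {out_dir}: {exc}") from exc
    library = make_default_library(
        bands,
        separation=config.separation,
        amplitude_sd=config.amplitude_sd,
        noise_sd=config.noise_sd,
    )
    rng = np.random.default_rng(seed)
    records = []
    for p in range(n_patients):
        patient_id = f"P{p + 1:02d}"
        prevalence = config.prevalence_for(p)
        n_samples = (
            samples_per_patient
            if isinstance(samples_per_patient, int)
            else samples_per_patient[p % len(samples_per_patient)]
        )
        for s in range(n_samples):
            sample_id = f"S{s + 1}"
            sdir = out_dir / patient_id / sample_id
            sdir.mkdir(parents=True, exist_ok=True)
            scene_seed = int(rng.integers(2**31))
            scene = make_scene(config, prevalence, scene_seed, rng)
            rendered = render_sample(scene, library, bands)
            tifffile.imwrite(sdir / "raw.tif", _to_counts(rendered.raw, scene))
            tifffile.imwrite(sdir / "white.tif", _to_counts(rendered.white, scene))
            tifffile.imwrite(sdir / "dark.tif", _to_counts(rendered.dark, scene))
            iio.imwrite(sdir / "annotation.png", rendered.annotation_rgb)
            iio.imwrite(sdir / "truth.png", rendered.truth)
            _control_points(scene, config.n_control_points).to_csv(
                sdir / "control_points.csv", index=False
            )
            organ = config.organs[(p * 7 + s) % len(config.organs)]
            rel = f"{patient_id}/{sample_id}"
            records.append(
                {
                    "patient_id": patient_id,
                    "sample_id": sample_id,
                    "organ": organ,
                    "raw_path": f"{rel}/raw.tif",
                    "white_path": f"{rel}/white.tif",
                    "dark_path": f"{rel}/dark.tif",
                    "annotation_path": f"{rel}/annotation.png",
                    "truth_path": f"{rel}/truth.png",
                    "control_points_path": f"{rel}/control_points.csv",
                }
            )
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame({"center_nm": bands.centers}).to_csv(out_dir / "bands.csv", index=False)
    return manifest


def _to_counts(frame: np.ndarray, scene: SceneSpec) -> np.ndarray:
    """Quantize a simulated frame to 12-bit-style integer camera counts."""
    return np.round(np.clip(frame, 0, scene.saturation_value)).astype(np.uint16)
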