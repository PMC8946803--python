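"""Raw-frame preprocessing: demosaic, reflectance calibration, normalization,
glare/background masking, edge erosion and 20x20 patch averaging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import ndimage

from hsi_oncopipe.bands import MOSAIC_SIZE, N_BANDS, BandTable
from hsi_oncopipe.errors import ConfigurationError, ContractError

logger = logging.getLogger(__name__)

DEFAULT_GLARE_THRESHOLD = 0.95
DEFAULT_BACKGROUND_THRESHOLD = 0.10
DEFAULT_EDGE_MARGIN = 20
DEFAULT_BLOCK_SIZE = 20
DEFAULT_MIN_VALID_FRACTION = 0.8
DENOMINATOR_EPS = 1e-6

# per-pixel annotation labels shared with the registration stage
LABEL_UNANNOTATED = 0
LABEL_NON_TUMOR = 1
LABEL_TUMOR = 2
LABEL_MIXED = 3


class Reason(IntEnum):
    """Exclusion reason codes for invalid pixels; VALID pixels carry none."""

    VALID = 0
    BACKGROUND = 1
    GLARE = 2
    EDGE = 3
    INVALID_REFERENCE = 4


@dataclass
class Hypercube:
    """rows x cols x 25 intensity array with its band table and stage tag."""

    data: np.ndarray
    bands: BandTable
    stage: str = "raw"  # {"raw", "reflectance", "normalized"}
    invalid_reference: np.ndarray | None = None  # rows x cols bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[2] != N_BANDS:
            raise ContractError(
                f"hypercube must be rows x cols x {N_BANDS}, got {self.data.shape}"
            )
        if self.stage not in {"raw", "reflectance", "normalized"}:
            raise ContractError(f"unknown stage {self.stage!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReferenceSet:
    """Demosaiced white and dark reference cubes used by the calibration step."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ContractError("white and dark reference shapes differ")
        bad = np.mean(self.white <= self.dark)
        if bad > 0.01:
            warnings.warn(
                f"{bad:.1%} of reference entries have white <= dark; "
                "they will be flagged invalid-reference",
                stacklevel=2,
            )


@dataclass
class ValidityMask:
    """Per-pixel validity with a single exclusion reason code per pixel."""

    reasons: np.ndarray  # rows x cols of Reason codes

    def __post_init__(self) -> None:
        self.reasons = np.asarray(self.reasons, dtype=np.uint8)

    @property
    def valid(self) -> np.ndarray:
        return self.reasons == Reason.VALID

    def counts(self) -> dict[str, int]:
        return {r.name.lower(): int(np.sum(self.reasons == r)) for r in Reason}


def demosaic(frame: np.ndarray, bands: BandTable) -> Hypercube:
    """Rearrange a raw 5x5 mosaic frame into a 25-band cube.

    Band ``b`` at output pixel (i, j) is the mosaic value at
    (5i + r_b, 5j + c_b).  The output spatial size is
    (floor(H/5), floor(W/5)); trailing rows/cols are dropped.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.shape[0] < MOSAIC_SIZE or frame.shape[1] < MOSAIC_SIZE:
        raise ContractError(f"mosaic frame must be 2-D and >= 5x5, got {frame.shape}")
    h, w = frame.shape
    rows, cols = h // MOSAIC_SIZE, w // MOSAIC_SIZE
    if h % MOSAIC_SIZE or w % MOSAIC_SIZE:
        logger.warning(
            "frame %dx%d is not a multiple of 5; dropping trailing rows/cols", h, w
        )
    cube = np.empty((rows, cols, N_BANDS), dtype=frame.dtype)
    for b, (r, c) in bands.mosaic_offsets.items():
        cube[:, :, b] = frame[r::MOSAIC_SIZE, c::MOSAIC_SIZE][:rows, :cols]
    return Hypercube(cube, bands, stage="raw")


def remosaic(cube: Hypercube) -> np.ndarray:
    """Inverse of :func:`demosaic` (exact on multiple-of-5 frames)."""
    rows, cols, _ = cube.shape
    frame = np.empty((rows * MOSAIC_SIZE, cols * MOSAIC_SIZE), dtype=cube.data.dtype)
    for b, (r, c) in cube.bands.mosaic_offsets.items():
        frame[r::MOSAIC_SIZE, c::MOSAIC_SIZE] = cube.data[:, :, b]
    return frame


def calibrate(raw: Hypercube, refs: ReferenceSet, eps: float = DENOMINATOR_EPS) -> Hypercube:
    """Relative reflectance: (raw - dark) / (white - dark), per pixel per band.

    Pixels where any band's denominator is <= ``eps`` are flagged
    invalid-reference and set to 0 in all bands.
    """
    if raw.stage != "raw":
        raise ContractError(f"calibrate expects a raw cube, got stage={raw.stage!r}")
    if refs.white.shape != raw.shape:
        raise ContractError(
            f"reference shape {refs.white.shape} != raw shape {raw.shape}"
        )
    denom = refs.white - refs.dark
    bad = denom <= eps
    safe = np.where(bad, 1.0, denom)
    refl = (raw.data.astype(float) - refs.dark) / safe
    invalid = bad.any(axis=2)
    refl[invalid] = 0.0
    return Hypercube(refl, raw.bands, stage="reflectance", invalid_reference=invalid)


def minmax_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Rescale one or many spectra to [0, 1] across their 25 bands.

    Accepts a 25-vector or an (..., 25) stack.  A flat spectrum
    (max == min) is degenerate and maps to all zeros.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.shape[-1] != N_BANDS:
        raise ContractError(f"expected trailing band axis of {N_BANDS}, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ContractError("spectrum contains non-finite values")
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    span = hi - lo
    flat = span == 0
    out = (x - lo) / np.where(flat, 1.0, span)
    return np.where(flat, 0.0, out)


def make_validity_mask(
    cube: Hypercube,
    glare_threshold: float = DEFAULT_GLARE_THRESHOLD,
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
) -> ValidityMask:
    """Flag glare (max over bands > glare_threshold) and background
    (mean over bands < background_threshold) pixels of a reflectance cube.

    Glare takes precedence; invalid-reference pixels from calibration keep
    their own reason code.
    """
    if cube.stage != "reflectance":
        raise ContractError("validity mask requires a reflectance cube")
    if glare_threshold <= background_threshold:
        raise ConfigurationError("glare threshold must exceed background threshold")
    reasons = np.zeros(cube.shape[:2], dtype=np.uint8)
    mean_r = cube.data.mean(axis=2)
    max_r = cube.data.max(axis=2)
    reasons[mean_r < background_threshold] = Reason.BACKGROUND
    reasons[max_r > glare_threshold] = Reason.GLARE
    if cube.invalid_reference is not None:
        reasons[cube.invalid_reference] = Reason.INVALID_REFERENCE
    return ValidityMask(reasons)


def erode_edges(mask: ValidityMask, margin: int = DEFAULT_EDGE_MARGIN) -> ValidityMask:
    """Erode the valid region by a square structuring element of radius ``margin``.

    Newly excluded pixels get reason EDGE; the image border counts as
    invalid, so each connected valid component shrinks independently.
    """
    if margin < 0:
        raise ConfigurationError("edge margin must be >= 0")
    if margin == 0:
        return ValidityMask(mask.reasons.copy())
    footprint = np.ones((2 * margin + 1, 2 * margin + 1), dtype=bool)
    eroded = ndimage.binary_erosion(mask.valid, structure=footprint, border_value=0)
    reasons = mask.reasons.copy()
    reasons[mask.valid & ~eroded] = Reason.EDGE
    return ValidityMask(reasons)


_PATCH_LABELS = {LABEL_TUMOR: "tumor", LABEL_NON_TUMOR: "non_tumor"}


def patch_average(
    cube: Hypercube,
    mask: ValidityMask,
    annotation: np.ndarray,
    block: int = DEFAULT_BLOCK_SIZE,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
    patient_id: str = "",
    sample_id: str = "",
) -> pd.DataFrame:
    """Average spectra over a grid of ``block`` x ``block`` pixel patches.

    The grid is anchored at (0, 0).  A patch is retained when its
    valid-pixel fraction is >= ``min_valid_fraction`` AND its valid
    annotated pixels carry a single label in {tumor, non_tumor}.  Patches
    touching mixed annotation, mixing both labels, or lacking annotation
    are kept with label ``excluded`` so stage bookkeeping stays auditable;
    downstream stages use only the tumor/non_tumor rows.
    """
    if block < 1:
        raise ConfigurationError("block size must be >= 1")
    annotation = np.asarray(annotation)
    if annotation.shape != cube.shape[:2]:
        raise ContractError("annotation shape does not match cube")
    rows, cols, _ = cube.shape
    valid = mask.valid
    records: list[dict] = []
    for br in range(int(np.ceil(rows / block))):
        for bc in range(int(np.ceil(cols / block))):
            rs, cs = br * block, bc * block
            v = valid[rs : rs + block, cs : cs + block]
            n_valid = int(v.sum())
            if n_valid < min_valid_fraction * block * block:
                continue
            ann = annotation[rs : rs + block, cs : cs + block][v]
            labels = set(np.unique(ann)) & {LABEL_TUMOR, LABEL_NON_TUMOR}
            if np.any(ann == LABEL_MIXED) or len(labels) != 1:
                label = "excluded"
            else:
                label = _PATCH_LABELS[labels.pop()]
            spectra = cube.data[rs : rs + block, cs : cs + block][v]
            records.append(
                {
                    "patient_id": patient_id,
                    "sample_id": sample_id,
                    "block_row": br,
                    "block_col": bc,
                    "n_valid": n_valid,
                    "label": label,
                    **dict(zip(cube.bands.column_names(), spectra.mean(axis=0))),
                }
            )
    if not any(r["label"] != "excluded" for r in records):
        warnings.warn("no retained patches for this sample", stacklevel=2)
    if not records:
        columns = [
            "patient_id", "sample_id", "block_row", "block_col", "n_valid", "label",
        ] + cube.bands.column_names()
        return pd.DataFrame(columns=columns)
    return pd.DataFrame.from_records(records)
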