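"""Annotation handling: HSV color thresholding of histology overlays and
control-point thin-plate-spline registration into hyperspectral coordinates.

Label conventions (shared with preprocessing): 0 unannotated, 1 non_tumor,
2 tumor, 3 mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RBFInterpolator
from skimage.color import rgb2hsv

from hsi_oncopipe.errors import ConfigurationError, ContractError
from hsi_oncopipe.preprocessing import (
    LABEL_MIXED,
    LABEL_NON_TUMOR,
    LABEL_TUMOR,
    LABEL_UNANNOTATED,
)

#: Default HSV windows, 8-bit OpenCV-style hue scale H in [0, 179].
#: (h_lo, h_hi, s_min, v_lo, v_hi); h_lo > h_hi means the window wraps at 179.
DEFAULT_HSV_WINDOWS: dict[str, tuple[float, float, float, float, float]] = {
    "tumor": (160, 5, 100, 60, 200),       # bordeaux
    "non_tumor": (100, 130, 100, 0, 255),  # blue
    "mixed": (45, 75, 100, 0, 255),        # green marker
}

_WINDOW_LABELS = {
    "tumor": LABEL_TUMOR,
    "non_tumor": LABEL_NON_TUMOR,
    "mixed": LABEL_MIXED,
}


@dataclass(frozen=True)
class ControlPointSet:
    """Paired source/destination pixel coordinates, (row, col), 0-based."""

    source: np.ndarray  # n x 2
    destination: np.ndarray  # n x 2

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.source, dtype=float))
        dst = np.atleast_2d(np.asarray(self.destination, dtype=float))
        if src.shape != dst.shape or src.shape[1] != 2:
            raise ContractError("control points must be matching n x 2 arrays")
        if len(src) < 3:
            raise ContractError("need >= 3 control-point pairs for a warp")
        # collinearity check: rank of centered points must be 2
        if np.linalg.matrix_rank(src - src.mean(axis=0)) < 2:
            raise ContractError("control points are collinear; warp is ill-posed")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "destination", dst)

    def __len__(self) -> int:
        return len(self.source)

    @classmethod
    def from_csv(cls, path) -> "ControlPointSet":
        """Read pairs from a CSV with columns x_src, y_src, x_dst, y_dst.

        x is the column coordinate and y the row coordinate.
        """
        df = pd.read_csv(path)
        src = np.column_stack([df["y_src"], df["x_src"]])
        dst = np.column_stack([df["y_dst"], df["x_dst"]])
        return cls(src, dst)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x_src": self.source[:, 1],
                "y_src": self.source[:, 0],
                "x_dst": self.destination[:, 1],
                "y_dst": self.destination[:, 0],
            }
        ).to_csv(path, index=False)

    def inverse(self) -> "ControlPointSet":
        return ControlPointSet(self.destination, self.source)


def _hue_in_window(h: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if lo <= hi:
        return (h >= lo) & (h <= hi)
    return (h >= lo) | (h <= hi)  # wrap-around window


def _windows_overlap(wa, wb) -> bool:
    grid = np.arange(180.0)
    in_a = _hue_in_window(grid, wa[0], wa[1])
    in_b = _hue_in_window(grid, wb[0], wb[1])
    sv_overlap = not (wa[4] < wb[3] or wb[4] < wa[3])
    return bool(np.any(in_a & in_b)) and sv_overlap


def hsv_masks(
    rgb: np.ndarray,
    windows: dict[str, tuple[float, float, float, float, float]] | None = None,
) -> np.ndarray:
    """Threshold an 8-bit RGB annotation image into a per-pixel label map.

    Pixels inside the tumor window map to 2, non_tumor to 1, mixed to 3;
    everything else (e.g. white background) stays 0 (unannotated).
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3 or rgb.dtype != np.uint8:
        raise ContractError("annotation image must be 8-bit RGB")
    windows = dict(windows or DEFAULT_HSV_WINDOWS)
    names = list(windows)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if _windows_overlap(windows[a], windows[b]):
                raise ConfigurationError(f"HSV windows {a!r} and {b!r} overlap")
    hsv = rgb2hsv(rgb[:, :, :3])
    h = hsv[:, :, 0] * 179.0
    s = hsv[:, :, 1] * 255.0
    v = hsv[:, :, 2] * 255.0
    labels = np.full(rgb.shape[:2], LABEL_UNANNOTATED, dtype=np.uint8)
    for name, (h_lo, h_hi, s_min, v_lo, v_hi) in windows.items():
        sel = _hue_in_window(h, h_lo, h_hi) & (s >= s_min) & (v >= v_lo) & (v <= v_hi)
        labels[sel] = _WINDOW_LABELS[name]
    return labels


def tps_warp(
    image: np.ndarray,
    points: ControlPointSet,
    order: int = 1,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Warp an image with a thin-plate-spline fit to the control points.

    The displacement field interpolates the pairs exactly (zero
    smoothing) and reduces to the affine map when the pairs are affine.
    Label masks should use ``order=0`` (nearest) to avoid label mixing;
    intensity images default to bilinear.

    The output samples the input at the TPS-interpolated source location
    of each destination pixel, so ``output[dst] == input[src]`` for every
    control-point pair.
    """
    image = np.asarray(image)
    shape = output_shape or image.shape[:2]
    try:
        interp = RBFInterpolator(
            points.destination, points.source, kernel="thin_plate_spline", smoothing=0.0
        )
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise ContractError(f"degenerate control points: {exc}") from exc
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dst_coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    src_coords = interp(dst_coords).T.reshape(2, *shape)
    if image.ndim == 2:
        return ndimage.map_coordinates(image, src_coords, order=order, mode="nearest")
    out = [
        ndimage.map_coordinates(image[:, :, k], src_coords, order=order, mode="nearest")
        for k in range(image.shape[2])
    ]
    return np.stack(out, axis=2)


def warp_displacement(points: ControlPointSet, shape: tuple[int, int]) -> np.ndarray:
    """Dense (2, rows, cols) field of source coordinates for each output pixel."""
    interp = RBFInterpolator(
        points.destination, points.source, kernel="thin_plate_spline", smoothing=0.0
    )
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    return interp(coords).T.reshape(2, *shape)


def label_patches(
    patch_table: pd.DataFrame, annotation: np.ndarray, block: int
) -> pd.Series:
    """Label each patch row of a PatchTable from a registered annotation mask.

    Applies the same purity rule as patch averaging: a block is tumor or
    non_tumor only if all its annotated pixels agree and none are mixed;
    otherwise it is excluded.
    """
    annotation = np.asarray(annotation)
    labels = []
    for _, row in patch_table.iterrows():
        rs, cs = int(row["block_row"]) * block, int(row["block_col"]) * block
        ann = annotation[rs : rs + block, cs : cs + block]
        present = set(np.unique(ann)) & {LABEL_TUMOR, LABEL_NON_TUMOR}
        if LABEL_MIXED in np.unique(ann) or len(present) != 1:
            labels.append("excluded")
        elif present == {LABEL_TUMOR}:
            labels.append("tumor")
        else:
            labels.append("non_tumor")
    return pd.Series(labels, index=patch_table.index, name="label")
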