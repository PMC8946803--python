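"""Spectral feature extraction (intensities, band differences, band ratios)
and univariate screening by Welch t-test and single-feature AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hsi_oncopipe.bands import BandTable, nearest_band
from hsi_oncopipe.errors import ConfigurationError, ContractError
from hsi_oncopipe.preprocessing import minmax_normalize

RATIO_EPS = 1e-9
RATIO_SENTINEL = np.nan


@dataclass(frozen=True)
class FeatureSpec:
    """One named spectral feature.

    kind 'intensity' uses one wavelength; 'derivative' is the raw
    intensity difference I(w2) - I(w1); 'ratio' is I(w1) / I(w2).
    """

    name: str
    kind: str
    wavelengths: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in {"intensity", "derivative", "ratio"}:
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")
        n = len(self.wavelengths)
        if (self.kind == "intensity" and n != 1) or (self.kind != "intensity" and n != 2):
            raise ConfigurationError(
                f"feature {self.name!r}: kind {self.kind!r} takes "
                f"{1 if self.kind == 'intensity' else 2} wavelengths, got {n}"
            )


def _intensity(w: float) -> FeatureSpec:
    return FeatureSpec(f"i{w:g}", "intensity", (w,))


def _derivative(w1: float, w2: float) -> FeatureSpec:
    return FeatureSpec(f"d{w1:g}_{w2:g}", "derivative", (w1, w2))


def _ratio(w1: float, w2: float) -> FeatureSpec:
    return FeatureSpec(f"q{w1:g}_{w2:g}", "ratio", (w1, w2))


def default_feature_specs() -> list[FeatureSpec]:
    """The default 19-feature panel: 9 intensities, 4 differences, 6 ratios."""
    return (
        [_intensity(w) for w in (697, 775, 799, 823, 863, 872, 901, 910, 923)]
        + [_derivative(*p) for p in ((684, 697), (882, 892), (923, 930), (943, 954))]
        + [_ratio(w, 910) for w in (676, 697, 762, 872, 923, 930)]
    )


def extract_features(
    spectrum: np.ndarray,
    specs: list[FeatureSpec],
    bands: BandTable,
    mode: str = "hybrid",
) -> np.ndarray:
    """Evaluate feature specs on one reflectance spectrum (or a stack).

    mode 'hybrid' (default): intensity features read the min-max
    normalized spectrum while derivative/ratio features read raw
    reflectance — normalization pins a zero into every spectrum, which
    destabilizes ratios.  'reflectance' and 'normalized' apply one scale
    to all features.  Ratio denominators below ``RATIO_EPS`` in magnitude
    yield NaN.
    """
    if mode not in {"hybrid", "reflectance", "normalized"}:
        raise ConfigurationError(f"unknown feature mode {mode!r}")
    x = np.asarray(spectrum, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if mode == "normalized":
        raw = norm = minmax_normalize(x)
    elif mode == "reflectance":
        raw = norm = x
    else:
        raw, norm = x, minmax_normalize(x)
    cols = []
    for spec in specs:
        idx = [nearest_band(w, bands) for w in spec.wavelengths]
        if spec.kind == "intensity":
            cols.append(norm[:, idx[0]])
        elif spec.kind == "derivative":
            cols.append(raw[:, idx[1]] - raw[:, idx[0]])
        else:
            denom = raw[:, idx[1]]
            safe = np.where(np.abs(denom) < RATIO_EPS, np.nan, denom)
            cols.append(raw[:, idx[0]] / safe)
    out = np.column_stack(cols)
    return out[0] if squeeze else out


def feature_table(
    patches: pd.DataFrame,
    bands: BandTable,
    specs: list[FeatureSpec] | None = None,
    mode: str = "hybrid",
) -> pd.DataFrame:
    """Build a per-patch feature table from a PatchTable.

    Keeps only tumor/non_tumor rows; output columns are the feature names
    plus patient_id, sample_id and label.
    """
    specs = specs if specs is not None else default_feature_specs()
    kept = patches[patches["label"].isin(["tumor", "non_tumor"])].reset_index(drop=True)
    spectra = kept[bands.column_names()].to_numpy(dtype=float)
    if len(kept):
        values = extract_features(spectra, specs, bands, mode=mode)
    else:
        values = np.empty((0, len(specs)))
    out = pd.DataFrame(values, columns=[s.name for s in specs])
    for col in ("patient_id", "sample_id", "label"):
        out[col] = kept[col].to_numpy() if len(kept) else pd.Series(dtype=object)
    return out


def ttest_screen(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Welch two-sample t-test per feature column; rows ranked by |t|."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ContractError("t-test screening needs exactly two classes")
    a, b = values[labels == classes[0]], values[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ContractError("each class needs >= 2 patches")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    df = pd.DataFrame({"feature": np.arange(values.shape[1]), "t": t, "p": p})
    return df.reindex(df["t"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def univariate_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC of one feature used directly as a classifier score.

    Computed as the Mann-Whitney U statistic normalized by
    n_pos * n_neg, with half credit for ties; orientation is chosen so
    the result is >= 0.5.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == 1] if labels.dtype.kind in "biu" else values[labels == "tumor"]
    neg = values[labels == 0] if labels.dtype.kind in "biu" else values[labels == "non_tumor"]
    if len(pos) == 0 or len(neg) == 0:
        raise ContractError("univariate AUC needs both classes present")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = u / (len(pos) * len(neg))
    return float(max(auc, 1.0 - auc))
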