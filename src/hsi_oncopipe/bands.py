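"""Band geometry of the 5x5 snapshot-mosaic sensor (25 NIR bands, 665-975 nm)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hsi_oncopipe.errors import ConfigurationError

N_BANDS = 25
MOSAIC_SIZE = 5
WAVELENGTH_MIN = 665.0
WAVELENGTH_MAX = 975.0

#: Wavelengths (nm) referenced by the default prognostic feature set.
FEATURE_WAVELENGTHS = (
    676, 684, 697, 762, 775, 799, 823, 863, 872,
    882, 892, 901, 910, 923, 930, 943, 954,
)

#: 8 filler centers completing a monotone 25-band table over 665-975 nm.
_FILLER_WAVELENGTHS = (665, 715, 733, 748, 811, 843, 965, 975)

DEFAULT_CENTERS = tuple(sorted(FEATURE_WAVELENGTHS + _FILLER_WAVELENGTHS))


def _default_offsets() -> dict[int, tuple[int, int]]:
    return {b: (b // MOSAIC_SIZE, b % MOSAIC_SIZE) for b in range(N_BANDS)}


@dataclass(frozen=True)
class BandTable:
    """25 band-center wavelengths plus their positions in the 5x5 mosaic cell.

    Parameters
    ----------
    centers_nm
        Strictly increasing wavelengths in nanometers, all within
        [665, 975].
    mosaic_offsets
        Map band index -> (row-offset, col-offset) within the repeating
        5x5 mosaic cell; must be a bijection onto {0..4} x {0..4}.
    """

    centers_nm: tuple[float, ...]
    mosaic_offsets: dict[int, tuple[int, int]] = field(default_factory=_default_offsets)

    def __post_init__(self) -> None:
        centers = tuple(float(c) for c in self.centers_nm)
        object.__setattr__(self, "centers_nm", centers)
        if len(centers) != N_BANDS:
            raise ConfigurationError(
                f"band table requires exactly {N_BANDS} centers, got {len(centers)}"
            )
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ConfigurationError("band centers must be strictly increasing")
        if centers[0] < WAVELENGTH_MIN or centers[-1] > WAVELENGTH_MAX:
            raise ConfigurationError(
                f"band centers must lie within [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}] nm"
            )
        offsets = set(self.mosaic_offsets.values())
        expected = {(r, c) for r in range(MOSAIC_SIZE) for c in range(MOSAIC_SIZE)}
        if set(self.mosaic_offsets) != set(range(N_BANDS)) or offsets != expected:
            raise ConfigurationError(
                "mosaic_offsets must map band indices 0..24 bijectively onto the 5x5 cell"
            )

    def __len__(self) -> int:
        return N_BANDS

    @property
    def centers(self) -> np.ndarray:
        return np.asarray(self.centers_nm, dtype=float)

    def column_names(self, prefix: str = "r") -> list[str]:
        """Stable per-band column names, e.g. ``r697`` for the 697 nm center."""
        return [f"{prefix}{c:g}" for c in self.centers_nm]


def make_band_table(centers_nm=None) -> BandTable:
    """Build a band table from 25 explicit centers, or the default table.

    The default table contains every wavelength used by the default
    feature set plus 8 filler centers spanning 665-975 nm.
    """
    if centers_nm is None:
        return BandTable(DEFAULT_CENTERS)
    return BandTable(tuple(centers_nm))


def nearest_band(wavelength_nm: float, bands: BandTable) -> int:
    """Index of the band center closest to ``wavelength_nm``.

    np.argmin returns the first minimizer, so ties break toward the
    lower band index.
    """
    from hsi_oncopipe.errors import ContractError

    if not 600.0 <= float(wavelength_nm) <= 1050.0:
        raise ContractError(f"wavelength {wavelength_nm} nm outside [600, 1050]")
    return int(np.argmin(np.abs(bands.centers - float(wavelength_nm))))
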