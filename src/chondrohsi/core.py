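"""Hyperspectral calibration and spectral-parameter images.

The imaging model is the standard two-point radiometric calibration: a raw
intensity cube ``I0`` is normalized against a white reference ``Iwhite`` and a
dark pattern ``Idark`` to reflectance ``IR = (I0 - Idark) / (Iwhite - Idark)``,
converted to absorbance ``A = -log10(IR)``, and reduced to three scalar images
per acquisition:

* ``A540``  – absorbance of the band nearest 540 nm (oxyhemoglobin Q-band
  region; elevated over thinned cartilage where subchondral blood shows
  through),
* ``A960``  – absorbance of the band nearest 960 nm (water absorption peak),
* ``TWI``   – tissue water index, a scaled window ratio
  ``100 * (mean A(955-980) / mean A(880-900) - s1) / (s2 - s1)`` clipped to
  [0, 100].

Reflectance is floored at ``EPSILON = 1e-6`` before the log so absorbance is
bounded by 6 and dark pixels cannot produce infinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    CalibrationError,
    EmptyWindowError,
    GridRangeError,
)

#: Reflectance floor applied before the log10; caps absorbance at 6.
EPSILON = 1e-6

#: Denominator floor for the TWI window ratio; pixels below it are flagged.
TWI_DENOM_FLOOR = 1e-9


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band centers, in nanometres."""

    band_centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.band_centers, dtype=float)
        if centers.ndim != 1 or centers.size < 2:
            raise ValueError("band_centers must be a 1-D array of >= 2 values")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        object.__setattr__(self, "band_centers", centers)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """500-1000 nm inclusive at 5 nm: 101 bands."""
        return cls.from_range(500.0, 1000.0, 5.0)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "WavelengthGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    @property
    def n_bands(self) -> int:
        return int(self.band_centers.size)

    @property
    def start(self) -> float:
        return float(self.band_centers[0])

    @property
    def stop(self) -> float:
        return float(self.band_centers[-1])

    def index_of(self, wavelength: float) -> int:
        """Index of the band center nearest ``wavelength``; ties go to the
        lower wavelength. Raises :class:`GridRangeError` outside the grid."""
        if not (self.start <= wavelength <= self.stop):
            raise GridRangeError(
                f"wavelength {wavelength} nm outside grid "
                f"[{self.start}, {self.stop}] nm"
            )
        dist = np.abs(self.band_centers - wavelength)
        # argmin returns the first (lower-wavelength) index on exact ties
        return int(np.argmin(dist))

    def window_indices(self, lo: float, hi: float) -> np.ndarray:
        """Indices of all bands with ``lo <= center <= hi`` (inclusive)."""
        if lo >= hi:
            raise ValueError(f"window lo {lo} must be < hi {hi}")
        if hi < self.start or lo > self.stop:
            raise GridRangeError(f"window [{lo}, {hi}] nm outside grid")
        idx = np.nonzero(
            (self.band_centers >= lo) & (self.band_centers <= hi)
        )[0]
        if idx.size == 0:
            raise EmptyWindowError(
                f"no band centers inside window [{lo}, {hi}] nm"
            )
        return idx

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.band_centers, other.band_centers)


def _check_cube(values: np.ndarray, grid: WavelengthGrid, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError(f"{what} must be rows x cols x bands")
    if values.shape[2] != grid.n_bands:
        raise ValueError(
            f"{what} has {values.shape[2]} bands but grid has {grid.n_bands}"
        )
    return values


@dataclass
class RawCube:
    """Raw sensor intensities, rows x cols x bands, arbitrary units."""

    intensities: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.intensities = _check_cube(self.intensities, self.grid, "RawCube")
        if np.any(self.intensities < 0):
            raise ValueError("raw intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class ReferenceSet:
    """White reference and dark pattern; either full cubes or 1x1xbands."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.ndim != 3 or self.dark.ndim != 3:
            raise ValueError("references must be 3-D (use 1x1xbands to broadcast)")


@dataclass
class ReflectanceCube:
    """Calibrated reflectance IR, clipped to [EPSILON, inf)."""

    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.values = _check_cube(self.values, self.grid, "ReflectanceCube")


@dataclass
class AbsorbanceCube:
    """Absorbance A = -log10(IR); bounded above by 6 via the EPSILON clip."""

    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.values = _check_cube(self.values, self.grid, "AbsorbanceCube")


@dataclass(frozen=True)
class TWIParams:
    """Scaling parameters of the tissue water index; s2 > s1."""

    s1: float = 0.4
    s2: float = 1.6

    def __post_init__(self) -> None:
        if not self.s2 > self.s1:
            raise ValueError(f"require s2 > s1, got s1={self.s1}, s2={self.s2}")

    def ratio_to_twi(self, ratio: np.ndarray | float) -> np.ndarray | float:
        """Unclipped TWI value for a window ratio."""
        return 100.0 * (np.asarray(ratio) - self.s1) / (self.s2 - self.s1)

    def twi_to_ratio(self, twi: np.ndarray | float) -> np.ndarray | float:
        """Inverse scaling: window ratio for a TWI value on the 0-100 scale."""
        return self.s1 + (np.asarray(twi) / 100.0) * (self.s2 - self.s1)


@dataclass
class IndexImage:
    """A single scalar parameter image (absorbance index or TWI)."""

    values: np.ndarray
    name: str
    #: pixels where the index is undefined (e.g. TWI denominator ~ 0)
    flags: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("IndexImage must be 2-D")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.values.shape:
                raise ValueError("flags shape must match values")


def calibrate_reflectance(raw: RawCube, refs: ReferenceSet) -> ReflectanceCube:
    """Two-point calibration IR = (I0 - Idark) / (Iwhite - Idark).

    The result is clipped below at EPSILON so a later log is finite.
    Raises :class:`CalibrationError` if the white reference does not exceed
    the dark pattern at any used element, naming the offending band.
    """
    denom = refs.white - refs.dark
    if np.any(denom <= 0):
        bad = np.unique(np.nonzero(denom <= 0)[-1])
        wls = raw.grid.band_centers[bad]
        raise CalibrationError(
            "white reference <= dark pattern at band(s) "
            f"{', '.join(f'{w:g} nm' for w in wls[:5])}"
            + ("..." if wls.size > 5 else "")
        )
    ratio = (raw.intensities - refs.dark) / denom
    return ReflectanceCube(np.clip(ratio, EPSILON, None), raw.grid)


def to_absorbance(refl: ReflectanceCube) -> AbsorbanceCube:
    """Absorbance A = -log10(IR), bounded by 6 through the EPSILON floor."""
    return AbsorbanceCube(-np.log10(np.clip(refl.values, EPSILON, None)), refl.grid)


def band_value(cube: AbsorbanceCube, wavelength: float) -> IndexImage:
    """Image of the band nearest ``wavelength`` (ties toward the lower band)."""
    i = cube.grid.index_of(wavelength)
    center = cube.grid.band_centers[i]
    return IndexImage(cube.values[:, :, i].copy(), name=f"A{center:g}")


def window_mean(cube: AbsorbanceCube, lo: float, hi: float) -> IndexImage:
    """Unweighted mean over all bands with lo <= center <= hi (inclusive)."""
    idx = cube.grid.window_indices(lo, hi)
    return IndexImage(
        cube.values[:, :, idx].mean(axis=2), name=f"mean{lo:g}-{hi:g}"
    )


def twi(cube: AbsorbanceCube, params: TWIParams = TWIParams()) -> IndexImage:
    """Tissue water index on the 0-100 scale.

    TWI = 100 * (mean A(955-980)/mean A(880-900) - s1) / (s2 - s1), clipped to
    [0, 100]. Pixels whose denominator window mean is <= 1e-9 are set to 0 and
    flagged rather than raising; downstream ROI statistics exclude them.
    """
    num = window_mean(cube, 955.0, 980.0).values
    den = window_mean(cube, 880.0, 900.0).values
    flags = den <= TWI_DENOM_FLOOR
    ratio = np.divide(num, den, out=np.zeros_like(num), where=~flags)
    values = np.clip(params.ratio_to_twi(ratio), 0.0, 100.0)
    values[flags] = 0.0
    return IndexImage(values, name="TWI", flags=flags)


def render_false_color(
    index: IndexImage,
    colormap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
) -> np.ndarray:
    """Deterministic false-color rendering of an index image to uint8 RGB.

    TWI images default to the fixed 0-100 display range; other indices default
    to their own data range. Raises ``ValueError`` for unknown colormap names.
    """
    import matplotlib

    try:
        cmap = matplotlib.colormaps[colormap]
    except KeyError as exc:
        raise ValueError(f"unknown colormap {colormap!r}") from exc
    if not np.all(np.isfinite(index.values)):
        raise ValueError("index image contains non-finite values")
    if vmin is None or vmax is None:
        if index.name.upper() == "TWI":
            vmin, vmax = 0.0, 100.0
        else:
            vmin = float(index.values.min()) if vmin is None else vmin
            vmax = float(index.values.max()) if vmax is None else vmax
    span = vmax - vmin if vmax > vmin else 1.0
    norm = np.clip((index.values - vmin) / span, 0.0, 1.0)
    rgba = cmap(norm, bytes=True)
    return np.asarray(rgba[..., :3])
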