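"""Spectrum container and arithmetic.

A :class:`Spectrum` holds one radiometric quantity sampled on a strictly
increasing wavelength grid (nm).  Missing values are NaN.  The operations
here are the numerical primitives behind reflectance assembly and quality
control: resampling to the common 1 nm grid, standardization to zero mean
and unit variance, windowed polynomial fits, and remote sensing reflectance
(R_rs) assembly from its radiometric components.

Quantities and units
--------------------
Rrs   remote sensing reflectance, sr^-1
Es    above-water downwelling irradiance, W m^-2 nm^-1
Lw    water-leaving radiance just above the surface, W m^-2 sr^-1 nm^-1
Lt    above-water upwelling radiance (includes surface-reflected sky
      light), W m^-2 sr^-1 nm^-1
Lsky  sky radiance used to correct Lt, W m^-2 sr^-1 nm^-1
Lu    upwelling radiance just below the surface, W m^-2 sr^-1 nm^-1
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np


class Quantity(str, enum.Enum):
    """Radiometric quantity identifiers, matching GLORIA column prefixes."""

    RRS = "Rrs"
    ES = "Es"
    LW = "Lw"
    LT = "Lt"
    LSKY = "Lsky"
    LU = "Lu"


class ZeroVarianceError(ValueError):
    """Raised when a spectrum cannot be standardized (constant or too short)."""


DEFAULT_GRID = np.arange(350, 901)


@dataclass
class Spectrum:
    """One radiometric quantity on a strictly increasing wavelength grid.

    Parameters
    ----------
    grid
        Wavelengths in nm, strictly increasing.
    values
        Quantity values aligned with ``grid``; NaN marks missing.
    quantity
        Which radiometric quantity this spectrum represents.
    """

    grid: np.ndarray
    values: np.ndarray
    quantity: Quantity = Quantity.RRS

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.values.ndim != 1:
            raise ValueError("grid and values must be one-dimensional")
        if self.grid.size != self.values.size:
            raise ValueError(
                f"grid has {self.grid.size} points but values has {self.values.size}"
            )
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def __len__(self) -> int:
        return int(self.grid.size)

    # -- accessors ---------------------------------------------------------

    def value_at(self, wavelength: float) -> float:
        """Value at the nearest grid point (NaN if the grid is empty)."""
        if self.grid.size == 0:
            return float("nan")
        i = int(np.argmin(np.abs(self.grid - wavelength)))
        return float(self.values[i])

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points inside [lo, hi] (inclusive)."""
        return (self.grid >= lo) & (self.grid <= hi)

    def covers(self, lo: float, hi: float) -> bool:
        """True if every integer wavelength in [lo, hi] is present and finite.

        Quality-control windows demand complete 1 nm coverage: a single
        missing wavelength inside the window makes the derived flag
        undeterminable (NA) rather than approximately computed.
        """
        wanted = np.arange(lo, hi + 1)
        present = self.grid[np.isfinite(self.values)]
        return bool(np.isin(wanted, present).all())

    def finite_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    def copy(self) -> "Spectrum":
        return Spectrum(self.grid.copy(), self.values.copy(), self.quantity)


@dataclass
class WindowFit:
    """Ordinary least-squares polynomial fit over an inclusive window.

    ``rmse`` uses n (number of fitted points) in the denominator, i.e. the
    plain root-mean-square of residuals.  ``slope`` is the first-degree
    coefficient (units per nm); for degree >= 2 it is the coefficient of the
    linear term of the fitted polynomial.
    """

    window: tuple[float, float]
    degree: int
    coefficients: np.ndarray  # ascending powers of (lambda)
    rmse: float
    slope: float
    n_points: int
    residuals: np.ndarray = field(repr=False, default=None)


@dataclass
class GlintConfig:
    """Air-water interface reflectance factor for sky radiance removal.

    ``rho`` is the dimensionless fraction of sky radiance reflected off the
    water surface into the sensor view.  The default 0.028 is the
    conventional flat-sea value for ~40 deg viewing geometry under low wind.
    """

    rho: float = 0.028

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    Wavelengths outside the native (finite) range become NaN: no
    extrapolation is ever performed, so short spectra stay short and
    downstream flags go to NA rather than being computed on invented data.
    """
    grid = np.asarray(grid, dtype=float)
    finite = np.isfinite(s.values)
    if finite.sum() < 2:
        raise ValueError("resampling requires at least 2 finite points")
    x, y = s.grid[finite], s.values[finite]
    out = np.interp(grid, x, y, left=np.nan, right=np.nan)
    return Spectrum(grid, out, s.quantity)


def standardize(s: Spectrum) -> Spectrum:
    """Standardize to zero mean and unit sample standard deviation.

    Statistics are computed over the full non-missing extent of the
    spectrum (not per QC window) using the n-1 sample standard deviation.
    Missing positions are preserved.
    """
    finite = np.isfinite(s.values)
    v = s.values[finite]
    if v.size < 2:
        raise ZeroVarianceError("need >= 2 finite values to standardize")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ZeroVarianceError("zero variance: constant spectrum")
    out = (s.values - float(np.mean(v))) / sd
    return Spectrum(s.grid.copy(), out, s.quantity)


def fit_window(s: Spectrum, window: tuple[float, float], degree: int) -> WindowFit:
    """OLS polynomial fit of value against wavelength inside an inclusive window."""
    lo, hi = window
    mask = s.window_mask(lo, hi) & np.isfinite(s.values)
    x = s.grid[mask]
    y = s.values[mask]
    if x.size < degree + 1:
        raise ValueError(
            f"window [{lo}, {hi}] has {x.size} points, need >= {degree + 1} for degree {degree}"
        )
    # Polynomial.fit maps the window onto [-1, 1] internally, which keeps the
    # degree-4 Vandermonde system well conditioned at lambda ~ 900.
    p = np.polynomial.Polynomial.fit(x, y, degree)
    fitted = p(x)
    resid = y - fitted
    rmse = float(np.sqrt(np.mean(resid**2)))
    coefs = p.convert().coef  # ascending powers in raw wavelength
    slope = float(coefs[1]) if degree >= 1 else 0.0
    return WindowFit(
        window=(lo, hi),
        degree=degree,
        coefficients=coefs,
        rmse=rmse,
        slope=slope,
        n_points=int(x.size),
        residuals=resid,
    )


def _guarded_ratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, int]:
    """Pointwise num/den with non-positive or missing denominators -> NaN."""
    bad = ~np.isfinite(den) | (den <= 0) | ~np.isfinite(num)
    n_nonpos = int(np.sum(np.isfinite(den) & (den <= 0) & np.isfinite(num)))
    out = np.full(num.shape, np.nan)
    ok = ~bad
    out[ok] = num[ok] / den[ok]
    return out, n_nonpos


def _require_common_grid(*spectra: Spectrum) -> None:
    g0 = spectra[0].grid
    for s in spectra[1:]:
        if s.grid.shape != g0.shape or not np.array_equal(s.grid, g0):
            raise ValueError("spectra must share a common wavelength grid")


def rrs_from_lw_es(lw: Spectrum, es: Spectrum) -> Spectrum:
    """R_rs = L_w / E_s, pointwise on a common grid.

    Positions where either input is missing, or E_s <= 0, become NaN; a
    warning reports the number of non-positive irradiance values guarded.
    """
    _require_common_grid(lw, es)
    out, n_bad = _guarded_ratio(lw.values, es.values)
    if n_bad:
        warnings.warn(
            f"{n_bad} wavelengths with Es <= 0 set to missing", stacklevel=2
        )
    return Spectrum(lw.grid.copy(), out, Quantity.RRS)


def rrs_from_lt_lsky_es(
    lt: Spectrum, lsky: Spectrum, es: Spectrum, cfg: GlintConfig | None = None
) -> Spectrum:
    """R_rs = (L_t - rho * L_sky) / E_s: above-water assembly with sky-glint removal.

    ``rho`` (GlintConfig) is the surface reflectance factor for sky
    radiance; with rho = 0 this reduces to L_t / E_s.  This is a convenience
    for assembling reflectance from raw component tables; it is not part of
    the QC flag computations.
    """
    cfg = cfg or GlintConfig()
    _require_common_grid(lt, lsky, es)
    num = lt.values - cfg.rho * lsky.values
    out, n_bad = _guarded_ratio(num, es.values)
    if n_bad:
        warnings.warn(
            f"{n_bad} wavelengths with Es <= 0 set to missing", stacklevel=2
        )
    return Spectrum(lt.grid.copy(), out, Quantity.RRS)
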