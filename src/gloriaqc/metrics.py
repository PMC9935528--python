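"""Per-spectrum ancillary metrics.

Oxygen A-band peak height, apparent visible wavelength (AVW), the 492/665 nm
normalized difference index (NDI), the QWIP score, CIE chromaticity
coordinates, and nearest-centroid optical water type assignment.

All shape metrics (oxygen peak height, AVW, NDI, QWIP) are invariant to
positive scaling of the reflectance spectrum, so they characterize spectral
shape independently of magnitude.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .spectra import Spectrum, ZeroVarianceError, standardize

# 4th-order polynomial predicting NDI(492, 665) from AVW, transcribed from
# the QWIP publication (Dierssen et al. 2022, Front. Remote Sens. 3:869611).
# Ascending powers of AVW (nm).
QWIP_COEFFICIENTS = np.array(
    [
        -5.449532e2,  # constant
        4.357838e0,  # avw
        -1.301670e-2,  # avw^2
        1.715532e-5,  # avw^3
        -8.399885e-9,  # avw^4
    ]
)

#: Bands of the normalized difference index used by QWIP, nm.
NDI_BANDS = (492.0, 665.0)

#: Visible window for AVW and chromaticity, nm (inclusive).
VISIBLE_WINDOW = (400.0, 700.0)

#: Windows defining the oxygen A-band baseline and search region, nm.
OXYGEN_LEFT_ANCHOR = (745.0, 755.0)
OXYGEN_RIGHT_ANCHOR = (775.0, 785.0)
OXYGEN_SEARCH = (759.0, 766.0)


@dataclass
class QCAncillary:
    """Ancillary QC metrics for one sample; NaN marks undefined values."""

    gloria_id: str
    oxygen_peak_height: float
    avw: float
    ndi: float
    qwip_score: float


@dataclass
class ChromaticityResult:
    """CIE 1931 (x, y) chromaticity and hue angle about the white point.

    The hue angle is measured counterclockwise from the positive x-axis at
    the equal-energy white point (1/3, 1/3), in degrees in (-180, 180].
    """

    x: float
    y: float
    hue_angle: float


@dataclass
class OWTCentroidSet:
    """User-supplied optical water type centroids on a common grid.

    The classifier is deliberately pluggable: centroids (e.g. transcribed
    from a published inland/coastal typology) are provided by the user, and
    the similarity metric is configurable (``"sam"`` spectral angle on
    area-normalized spectra, or ``"euclidean"`` on area-normalized spectra).
    """

    class_ids: list[int]
    grid: np.ndarray
    centroids: np.ndarray  # shape (n_classes, n_wavelengths)
    metric: str = "sam"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.class_ids) != self.centroids.shape[0]:
            raise ValueError("one centroid per class id required")
        if self.centroids.shape[1] != self.grid.size:
            raise ValueError("centroids must lie on the common grid")
        if self.metric not in ("sam", "euclidean"):
            raise ValueError(f"unknown similarity metric {self.metric!r}")


# ---------------------------------------------------------------------------
# oxygen A-band
# ---------------------------------------------------------------------------


def oxygen_peak_height(
    s: Spectrum,
    search: tuple[float, float] = OXYGEN_SEARCH,
) -> float:
    """Height of the oxygen A-band artifact near 762 nm, standardized units.

    The spectrum is standardized (zero mean, unit SD over its full finite
    extent).  A straight baseline joins the anchor points (750 nm, median of
    standardized values over 745-755 nm) and (780 nm, median over
    775-785 nm); the metric is the maximum absolute deviation of the
    standardized spectrum from this baseline inside the search window
    (default 759-766 nm).  Sign-agnostic: a local maximum or minimum near
    762 nm registers equally.

    Returns NaN when 745-785 nm is not fully covered or the spectrum cannot
    be standardized.
    """
    if not s.covers(OXYGEN_LEFT_ANCHOR[0], OXYGEN_RIGHT_ANCHOR[1]):
        return float("nan")
    try:
        z = standardize(s)
    except ZeroVarianceError:
        return float("nan")
    left = float(np.median(z.values[z.window_mask(*OXYGEN_LEFT_ANCHOR)]))
    right = float(np.median(z.values[z.window_mask(*OXYGEN_RIGHT_ANCHOR)]))
    x0 = 0.5 * (OXYGEN_LEFT_ANCHOR[0] + OXYGEN_LEFT_ANCHOR[1])  # 750
    x1 = 0.5 * (OXYGEN_RIGHT_ANCHOR[0] + OXYGEN_RIGHT_ANCHOR[1])  # 780
    mask = z.window_mask(*search) & np.isfinite(z.values)
    lam = z.grid[mask]
    baseline = left + (right - left) * (lam - x0) / (x1 - x0)
    return float(np.max(np.abs(z.values[mask] - baseline)))


# ---------------------------------------------------------------------------
# AVW / NDI / QWIP
# ---------------------------------------------------------------------------


def avw(s: Spectrum) -> float:
    """Apparent visible wavelength: R_rs-weighted harmonic mean of 400-700 nm.

    AVW = sum(R_rs) / sum(R_rs / lambda) over the inclusive 1 nm visible
    window.  Undefined (NaN) when the window is not fully covered or the
    denominator is non-positive.
    """
    if not s.covers(*VISIBLE_WINDOW):
        return float("nan")
    mask = s.window_mask(*VISIBLE_WINDOW)
    r = s.values[mask]
    lam = s.grid[mask]
    den = float(np.sum(r / lam))
    if not np.isfinite(den) or den <= 0:
        return float("nan")
    return float(np.sum(r) / den)


def ndi(s: Spectrum, bands: tuple[float, float] = NDI_BANDS) -> float:
    """Normalized difference index (R(665) - R(492)) / (R(665) + R(492)).

    Band values are read at the nearest 1 nm grid points.  NaN when either
    band is missing or the denominator is zero.
    """
    b_lo, b_hi = bands
    r_lo = s.value_at(b_lo)
    r_hi = s.value_at(b_hi)
    if not (np.isfinite(r_lo) and np.isfinite(r_hi)):
        return float("nan")
    den = r_hi + r_lo
    if den == 0:
        return float("nan")
    return float((r_hi - r_lo) / den)


def qwip_predicted_ndi(avw_nm: float, coeffs: np.ndarray | None = None) -> float:
    """NDI predicted from AVW by the 4th-order QWIP central-tendency polynomial."""
    c = QWIP_COEFFICIENTS if coeffs is None else np.asarray(coeffs, dtype=float)
    return float(np.polynomial.polynomial.polyval(avw_nm, c))


def qwip_score(s: Spectrum, coeffs: np.ndarray | None = None) -> float:
    """QWIP score: observed NDI minus the NDI predicted from the spectrum's AVW.

    Spectra of typical aquatic shape score near zero; |score| > 0.2 marks a
    shape outside the central tendency of well-formed reflectance spectra.
    """
    a = avw(s)
    n = ndi(s)
    if not (np.isfinite(a) and np.isfinite(n)):
        return float("nan")
    return n - qwip_predicted_ndi(a, coeffs)


# ---------------------------------------------------------------------------
# chromaticity
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=1)
def _cmf_1nm() -> tuple[np.ndarray, np.ndarray]:
    """CIE 1931 2-degree color-matching functions interpolated to 1 nm."""
    path = resources.files("gloriaqc.data").joinpath("cie_1931_2deg_cmf_5nm.csv")
    raw = np.loadtxt(str(path), delimiter=",", comments="#", skiprows=4)
    lam5, cmf5 = raw[:, 0], raw[:, 1:]
    lam1 = np.arange(lam5[0], lam5[-1] + 1)
    cmf1 = np.column_stack([np.interp(lam1, lam5, cmf5[:, j]) for j in range(3)])
    return lam1, cmf1


def chromaticity(
    s: Spectrum, window: tuple[float, float] = VISIBLE_WINDOW
) -> ChromaticityResult:
    """CIE 1931 (x, y) chromaticity of a reflectance spectrum.

    Tristimulus values are discrete sums of R_rs against the CIE 1931
    2-degree color-matching functions over the visible window, each channel
    normalized by its own CMF sum over that window (equal-energy
    normalization).  A spectrally flat spectrum therefore lands exactly on
    the equal-energy white point (1/3, 1/3), and the result is invariant to
    positive scaling of the spectrum.

    Returns NaN coordinates when the window is not covered or X+Y+Z <= 0.
    """
    nan_result = ChromaticityResult(float("nan"), float("nan"), float("nan"))
    if not s.covers(*window):
        return nan_result
    mask = s.window_mask(*window)
    lam = s.grid[mask]
    r = s.values[mask]
    cmf_lam, cmf = _cmf_1nm()
    idx = np.searchsorted(cmf_lam, lam)
    w = cmf[idx]  # (n, 3)
    sums = w.sum(axis=0)
    xyz = (r[:, None] * w).sum(axis=0) / sums
    total = float(xyz.sum())
    if not np.isfinite(total) or total <= 0:
        return nan_result
    x, y = float(xyz[0] / total), float(xyz[1] / total)
    hue = float(np.degrees(np.arctan2(y - 1.0 / 3.0, x - 1.0 / 3.0)))
    return ChromaticityResult(x=x, y=y, hue_angle=hue)


# ---------------------------------------------------------------------------
# optical water types
# ---------------------------------------------------------------------------


def _area_normalize(v: np.ndarray) -> np.ndarray:
    area = np.sum(np.abs(v))
    if area == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return v / area


def assign_owt(s: Spectrum, centroids: OWTCentroidSet) -> int:
    """Assign a spectrum to the nearest optical water type centroid.

    Both the spectrum (restricted to the centroid grid) and each centroid
    are area-normalized; distance is the spectral angle (default) or
    Euclidean distance.  Ties break deterministically to the lowest class
    id.  Scale-invariant: a*centroid_k maps to class k for any a > 0.
    """
    if centroids.centroids.shape[0] == 0:
        raise ValueError("no centroids supplied")
    idx = np.searchsorted(s.grid, centroids.grid)
    idx = np.clip(idx, 0, s.grid.size - 1)
    if not np.allclose(s.grid[idx], centroids.grid):
        raise ValueError("spectrum does not cover the centroid grid")
    v = s.values[idx]
    if not np.all(np.isfinite(v)):
        raise ValueError("spectrum has missing values on the centroid grid")
    v = _area_normalize(v)
    order = np.argsort(centroids.class_ids, kind="stable")
    best_class, best_d = None, np.inf
    for i in order:
        c = _area_normalize(centroids.centroids[i])
        if centroids.metric == "sam":
            cosang = np.dot(v, c) / (np.linalg.norm(v) * np.linalg.norm(c))
            d = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
        else:
            d = float(np.linalg.norm(v - c))
        if d < best_d - 1e-15:
            best_d, best_class = d, centroids.class_ids[i]
    return int(best_class)


def ancillary_for(
    gloria_id: str, s: Spectrum, qwip_coeffs: np.ndarray | None = None
) -> QCAncillary:
    """Compute the full ancillary metric row for one sample."""
    return QCAncillary(
        gloria_id=gloria_id,
        oxygen_peak_height=oxygen_peak_height(s),
        avw=avw(s),
        ndi=ndi(s),
        qwip_score=qwip_score(s, qwip_coeffs),
    )
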