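"""Procedural quality-control flags for reflectance spectra.

Each flag is tri-state: 1 (issue detected), 0 (test passed), or None (NA:
the spectrum did not include the wavelength range the test requires, or a
degeneracy such as zero variance made the test undeterminable).  All
thresholds are strict inequalities.

Flag suite
----------
Noisy_red          degree-4 fit over 750-900 nm of the standardized
                   spectrum; RMSE > 0.2
Noisy_blue         same over 350-400 nm; RMSE > 0.15
Baseline_shift     shifted-up (min/median > 0.6) or shifted-down
                   (negative-value patterns, raw sr^-1 units)
Oxygen_signal      oxygen A-band peak height > 0.1 (standardized units)
Negative_uv_slope  line fit over 350-420 nm of the standardized spectrum;
                   slope < -0.005 per nm
QWIP_fail          |QWIP score| > 0.2
Suspect            expert elicitation; never computed here, accepted as an
                   external input
Flagged            1 iff any component flag (including Suspect) is 1
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from . import metrics
from .spectra import Spectrum, Quantity, ZeroVarianceError, fit_window, standardize

logger = logging.getLogger(__name__)

Flag = int | None  # tri-state: 0, 1, or None (NA)

#: Flag columns in distribution order.
FLAG_COLUMNS = [
    "Noisy_red",
    "Noisy_blue",
    "Baseline_shift",
    "Oxygen_signal",
    "Negative_uv_slope",
    "QWIP_fail",
    "Suspect",
    "Flagged",
]

# thresholds, strict inequalities exactly as distributed
NOISY_RED_WINDOW = (750.0, 900.0)
NOISY_RED_RMSE = 0.2
NOISY_BLUE_WINDOW = (350.0, 400.0)
NOISY_BLUE_RMSE = 0.15
UPSHIFT_MIN_TO_MEDIAN = 0.6
DOWNSHIFT_MIN_NEGATIVES = 20
DOWNSHIFT_NIR_WINDOW = (765.0, 900.0)
DOWNSHIFT_NIR_SLOPE = -8.75e-7  # sr^-1 nm^-1, raw units
DOWNSHIFT_NIR_NEG_FRAC = 0.5
DOWNSHIFT_NIR_NEG_FRAC_ALONE = 0.7
DOWNSHIFT_UV_WINDOW = (350.0, 450.0)
DOWNSHIFT_UV_MIN_NEGATIVES = 20
OXYGEN_HEIGHT = 0.1
UV_SLOPE_WINDOW = (350.0, 420.0)
UV_SLOPE = -0.005  # standardized units per nm
QWIP_ABS = 0.2


@dataclass
class QCResult:
    """Tri-state flags for one sample; ``flagged`` is the aggregate."""

    gloria_id: str
    noisy_red: Flag
    noisy_blue: Flag
    baseline_shift: Flag
    oxygen_signal: Flag
    negative_uv_slope: Flag
    qwip_fail: Flag
    suspect: Flag
    flagged: Flag

    def components(self) -> list[Flag]:
        return [
            self.noisy_red,
            self.noisy_blue,
            self.baseline_shift,
            self.oxygen_signal,
            self.negative_uv_slope,
            self.qwip_fail,
            self.suspect,
        ]


PROCEDURAL_FIELDS = [f.name for f in fields(QCResult)][1:7]


def _rmse_flag(s: Spectrum, window: tuple[float, float], threshold: float) -> Flag:
    if not s.covers(*window):
        return None
    try:
        z = standardize(s)
    except ZeroVarianceError:
        return None
    fit = fit_window(z, window, degree=4)
    return int(fit.rmse > threshold)


def flag_noisy_red(s: Spectrum) -> Flag:
    """High-frequency variability near the red end (750-900 nm)."""
    return _rmse_flag(s, NOISY_RED_WINDOW, NOISY_RED_RMSE)


def flag_noisy_blue(s: Spectrum) -> Flag:
    """High-frequency variability near the blue end (350-400 nm)."""
    return _rmse_flag(s, NOISY_BLUE_WINDOW, NOISY_BLUE_RMSE)


def flag_baseline_shift(s: Spectrum) -> Flag:
    """Additive baseline offsets, evaluated on the raw R_rs spectrum (sr^-1).

    Shifted up: min(R_rs) / median(R_rs) > 0.6 with a positive median —
    a spectrum whose baseline never drops far below its bulk level.

    Shifted down: at least 20 negative values over the available extent,
    combined with any of
      (a) raw linear slope over 765-900 nm < -8.75e-7 sr^-1 nm^-1 and >50%
          negative values in that window;
      (b) >70% negative values in 765-900 nm;
      (c) at least 20 negative values within 350-450 nm.

    NA when no branch is determinable (non-positive median and no covered
    down-shift window).
    """
    finite = np.isfinite(s.values)
    v = s.values[finite]
    if v.size == 0:
        return None

    determinable = False
    median = float(np.median(v))
    if median > 0:
        determinable = True
        if float(np.min(v)) / median > UPSHIFT_MIN_TO_MEDIAN:
            return 1

    n_neg_total = int(np.sum(v < 0))

    nir_ok = s.covers(*DOWNSHIFT_NIR_WINDOW)
    uv_ok = s.covers(*DOWNSHIFT_UV_WINDOW)
    if nir_ok or uv_ok:
        determinable = True
    if n_neg_total >= DOWNSHIFT_MIN_NEGATIVES:
        if nir_ok:
            mask = s.window_mask(*DOWNSHIFT_NIR_WINDOW) & finite
            frac_neg = float(np.mean(s.values[mask] < 0))
            slope = fit_window(s, DOWNSHIFT_NIR_WINDOW, degree=1).slope
            if slope < DOWNSHIFT_NIR_SLOPE and frac_neg > DOWNSHIFT_NIR_NEG_FRAC:
                return 1
            if frac_neg > DOWNSHIFT_NIR_NEG_FRAC_ALONE:
                return 1
        if uv_ok:
            mask = s.window_mask(*DOWNSHIFT_UV_WINDOW) & finite
            if int(np.sum(s.values[mask] < 0)) >= DOWNSHIFT_UV_MIN_NEGATIVES:
                return 1

    return 0 if determinable else None


def flag_oxygen(s: Spectrum) -> Flag:
    """Oxygen A-band artifact near 762 nm: peak height > 0.1."""
    height = metrics.oxygen_peak_height(s)
    if not np.isfinite(height):
        return None
    return int(height > OXYGEN_HEIGHT)


def flag_negative_uv_slope(s: Spectrum) -> Flag:
    """Negative UV-blue slope of the standardized spectrum over 350-420 nm."""
    if not s.covers(*UV_SLOPE_WINDOW):
        return None
    try:
        z = standardize(s)
    except ZeroVarianceError:
        return None
    fit = fit_window(z, UV_SLOPE_WINDOW, degree=1)
    return int(fit.slope < UV_SLOPE)


def flag_qwip(s: Spectrum, coeffs: np.ndarray | None = None) -> Flag:
    """QWIP score outside |0.2| (strict)."""
    score = metrics.qwip_score(s, coeffs)
    if not np.isfinite(score):
        return None
    return int(abs(score) > QWIP_ABS)


def aggregate(
    gloria_id: str,
    noisy_red: Flag,
    noisy_blue: Flag,
    baseline_shift: Flag,
    oxygen_signal: Flag,
    negative_uv_slope: Flag,
    qwip_fail: Flag,
    suspect: Flag = None,
) -> QCResult:
    """Combine component flags into a QCResult with the aggregate bit.

    ``flagged`` is 1 if any component (including the externally supplied
    Suspect flag) is 1; NA only if every component is NA; otherwise 0 — an
    NA component does not assert presence of a problem.
    """
    comps = [
        noisy_red,
        noisy_blue,
        baseline_shift,
        oxygen_signal,
        negative_uv_slope,
        qwip_fail,
        suspect,
    ]
    if any(c == 1 for c in comps):
        flagged: Flag = 1
    elif all(c is None for c in comps):
        flagged = None
    else:
        flagged = 0
    return QCResult(
        gloria_id,
        noisy_red,
        noisy_blue,
        baseline_shift,
        oxygen_signal,
        negative_uv_slope,
        qwip_fail,
        suspect,
        flagged,
    )


def qc_spectrum(
    gloria_id: str, s: Spectrum, suspect: Flag = None
) -> tuple[QCResult, metrics.QCAncillary]:
    """Run the full procedural flag suite plus ancillary metrics on one spectrum."""
    anc = metrics.ancillary_for(gloria_id, s)
    result = aggregate(
        gloria_id,
        noisy_red=flag_noisy_red(s),
        noisy_blue=flag_noisy_blue(s),
        baseline_shift=flag_baseline_shift(s),
        oxygen_signal=flag_oxygen(s),
        negative_uv_slope=flag_negative_uv_slope(s),
        qwip_fail=flag_qwip(s),
        suspect=suspect,
    )
    return result, anc


def run_qc(table, suspects: dict[str, Flag] | None = None):
    """Apply the flag suite to every spectrum of an R_rs table.

    Parameters
    ----------
    table
        A ``SpectralTable`` with quantity Rrs (see :mod:`gloriaqc.io`).
    suspects
        Optional mapping GLORIA_ID -> Suspect flag from the distributed
        flag file; ids not in the mapping get Suspect = NA.

    Returns
    -------
    (list of QCResult, list of QCAncillary), in table id order.
    """
    if table.quantity != Quantity.RRS:
        raise ValueError(f"QC flags are defined on Rrs tables, got {table.quantity}")
    suspects = suspects or {}
    results: list[QCResult] = []
    ancillary: list[metrics.QCAncillary] = []
    for gid in table.ids:
        res, anc = qc_spectrum(gid, table.spectrum(gid), suspects.get(gid))
        results.append(res)
        ancillary.append(anc)
    counts = flag_counts(results)
    logger.info("QC complete for %d spectra: %s", len(results), counts)
    return results, ancillary


def flag_counts(results: list[QCResult]) -> dict[str, int]:
    """Number of spectra with each flag raised (NA does not count)."""
    keys = PROCEDURAL_FIELDS + ["suspect", "flagged"]
    out = {k: 0 for k in keys}
    for r in results:
        for k in keys:
            if getattr(r, k) == 1:
                out[k] += 1
    return out
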