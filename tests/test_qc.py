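"""Procedural QC flag suite: thresholds, NA semantics, aggregation."""

import numpy as np
import pytest

from gloriaqc import (
    Quantity,
    SpectralTable,
    Spectrum,
    aggregate,
    flag_baseline_shift,
    flag_counts,
    flag_negative_uv_slope,
    flag_noisy_blue,
    flag_noisy_red,
    flag_oxygen,
    flag_qwip,
    ndi,
    run_qc,
)
from gloriaqc.qc import qc_spectrum

from conftest import GRID, make_spectrum
from test_metrics import calibrated_spike_spectrum


def _with_alternating(base, lo, hi, amp_std):
    """Add alternating +/- residuals (standardized units) inside [lo, hi]."""
    v = base.values.copy()
    sd = float(np.std(v[np.isfinite(v)], ddof=1))
    mask = (GRID >= lo) & (GRID <= hi)
    v[mask] += amp_std * sd * (-1.0) ** np.arange(mask.sum())
    return make_spectrum(v)


class TestNoiseFlags:
    def test_smooth_spectrum_passes(self, smooth_spectrum):
        assert flag_noisy_red(smooth_spectrum) == 0
        assert flag_noisy_blue(smooth_spectrum) == 0

    def test_red_alternating_residuals_flagged(self, smooth_spectrum):
        # +/-0.3 standardized alternation over 750-900: RMSE ~ 0.29 > 0.2
        assert flag_noisy_red(_with_alternating(smooth_spectrum, 750, 900, 0.3)) == 1

    def test_blue_alternating_residuals_flagged(self, smooth_spectrum):
        # +/-0.25 over 350-400: RMSE ~ 0.24 > 0.15
        assert flag_noisy_blue(_with_alternating(smooth_spectrum, 350, 400, 0.25)) == 1

    def test_short_red_coverage_gives_na(self):
        s = Spectrum(np.arange(400.0, 751.0), np.linspace(1, 2, 351) ** 2)
        assert flag_noisy_red(s) is None

    def test_short_blue_coverage_gives_na(self):
        s = Spectrum(np.arange(400.0, 901.0), np.linspace(1, 2, 501) ** 2)
        assert flag_noisy_blue(s) is None

    def test_constant_spectrum_gives_na(self):
        assert flag_noisy_red(make_spectrum(np.full(GRID.size, 2.0))) is None


class TestBaselineShift:
    def test_constant_positive_spectrum_is_upshifted(self):
        # min equals median, ratio 1 > 0.6
        assert flag_baseline_shift(make_spectrum(np.full(GRID.size, 0.01))) == 1

    def test_twenty_uv_negatives_is_downshifted(self, smooth_spectrum):
        v = smooth_spectrum.values.copy()
        v[(GRID >= 350) & (GRID <= 369)] = -1e-4  # exactly 20 negatives
        assert flag_baseline_shift(make_spectrum(v)) == 1

    def test_nineteen_uv_negatives_not_flagged(self, smooth_spectrum):
        v = smooth_spectrum.values.copy()
        v[(GRID >= 350) & (GRID <= 368)] = -1e-4
        assert flag_baseline_shift(make_spectrum(v)) == 0

    def test_negative_nir_majority_is_downshifted(self, smooth_spectrum):
        v = smooth_spectrum.values.copy()
        nir = (GRID >= 765) & (GRID <= 900)
        v[nir] = -1e-5  # 100% negative in 765-900, 136 >= 20 negatives
        assert flag_baseline_shift(make_spectrum(v)) == 1

    def test_peaked_spectrum_passes(self, smooth_spectrum):
        assert flag_baseline_shift(smooth_spectrum) == 0

    def test_raw_units_slope_branch_not_scale_invariant(self, smooth_spectrum):
        # NIR replaced by a line with slope -2e-6 sr^-1 nm^-1 crossing zero
        # at 826 nm: ~54% of 765-900 negative, so only the slope branch can
        # fire.  Scaling by 1/10 moves the slope above the raw-unit
        # threshold (-8.75e-7) and the flag flips -- deliberately not
        # scale-invariant.
        v = smooth_spectrum.values / float(np.max(smooth_spectrum.values)) * 0.01
        nir = (GRID >= 765) & (GRID <= 900)
        v = v.copy()
        v[nir] = -2e-6 * (GRID[nir] - 826.0)
        v[(GRID >= 350) & (GRID <= 360)] = -1e-7  # top up the 20-negative gate
        s1 = make_spectrum(v)
        s2 = make_spectrum(v / 10.0)
        assert flag_baseline_shift(s1) == 1
        assert flag_baseline_shift(s2) == 0


class TestOxygenFlag:
    def test_linear_region_passes(self):
        assert flag_oxygen(make_spectrum(0.001 + 1e-5 * (GRID - 350.0))) == 0

    def test_spike_above_threshold_flagged(self):
        assert flag_oxygen(calibrated_spike_spectrum(762.0, 0.25)) == 1

    def test_spike_below_threshold_passes(self):
        assert flag_oxygen(calibrated_spike_spectrum(762.0, 0.08)) == 0

    def test_spectrum_ending_at_750_gives_na(self):
        s = Spectrum(np.arange(350.0, 751.0), np.linspace(1, 2, 401) ** 2)
        assert flag_oxygen(s) is None


class TestNegativeUVSlope:
    def test_flat_blue_end_passes(self, smooth_spectrum):
        assert flag_negative_uv_slope(smooth_spectrum) == 0

    def test_steep_uv_decrease_flagged(self):
        # 0.02 -> 0.001 sr^-1 across 350-420 then flat: standardized slope
        # is far below -0.005 per nm
        v = np.full(GRID.size, 0.001)
        uv = GRID <= 420
        v[uv] = 0.02 + (0.001 - 0.02) * (GRID[uv] - 350.0) / 70.0
        assert flag_negative_uv_slope(make_spectrum(v)) == 1

    def test_spectrum_starting_at_400_gives_na(self):
        s = Spectrum(np.arange(400.0, 901.0), np.linspace(2, 1, 501) ** 2)
        assert flag_negative_uv_slope(s) is None


class TestQWIPFlag:
    def test_score_zero_by_construction_passes(self, smooth_spectrum):
        coeffs = np.array([ndi(smooth_spectrum), 0.0, 0.0, 0.0, 0.0])
        assert flag_qwip(smooth_spectrum, coeffs) == 0

    def _exact_ndi_half_spectrum(self):
        # R(492)=1, R(665)=3 gives NDI = 2/4 = 0.5 with no rounding
        v = np.full(GRID.size, 1.0)
        v[GRID == 665.0] = 3.0
        return make_spectrum(v)

    def test_score_exactly_at_threshold_passes(self):
        # strict inequality: |score| == 0.2 exactly is not flagged.
        # NDI is exactly 0.5 and 0.5 - 0.3 == 0.2 in binary floating point.
        s = self._exact_ndi_half_spectrum()
        coeffs = np.array([0.3, 0.0, 0.0, 0.0, 0.0])
        from gloriaqc import qwip_score

        assert qwip_score(s, coeffs) == 0.2
        assert flag_qwip(s, coeffs) == 0

    def test_score_just_beyond_threshold_flagged(self):
        s = self._exact_ndi_half_spectrum()
        coeffs = np.array([0.2999, 0.0, 0.0, 0.0, 0.0])
        assert flag_qwip(s, coeffs) == 1

    def test_partial_visible_coverage_gives_na(self):
        s = Spectrum(np.arange(400.0, 601.0), np.ones(201) + np.arange(201) * 1e-3)
        assert flag_qwip(s) is None


class TestAggregate:
    def test_all_clear(self):
        r = aggregate("a", 0, 0, 0, 0, 0, 0, suspect=0)
        assert r.flagged == 0

    def test_single_component_raises_aggregate(self):
        r = aggregate("a", 0, 0, 0, 1, 0, 0, suspect=None)
        assert r.flagged == 1

    def test_na_component_does_not_assert_presence(self):
        r = aggregate("a", 0, None, 0, 0, 0, 0, suspect=None)
        assert r.flagged == 0

    def test_all_na_gives_na(self):
        r = aggregate("a", None, None, None, None, None, None, suspect=None)
        assert r.flagged is None

    def test_external_suspect_feeds_aggregate(self):
        r = aggregate("a", 0, 0, 0, 0, 0, 0, suspect=1)
        assert r.flagged == 1 and r.suspect == 1


class TestScaleInvariance:
    @pytest.mark.parametrize("scale", [1e-3, 1.0, 1e4])
    def test_standardized_flags_invariant(self, smooth_spectrum, scale):
        base = smooth_spectrum
        scaled = Spectrum(base.grid, scale * base.values)
        for flag in (flag_noisy_red, flag_noisy_blue, flag_oxygen, flag_negative_uv_slope):
            assert flag(scaled) == flag(base)

    def test_shape_metric_flags_invariant_with_artifact(self, smooth_spectrum):
        noisy = _with_alternating(smooth_spectrum, 750, 900, 0.3)
        scaled = Spectrum(noisy.grid, 250.0 * noisy.values)
        assert flag_noisy_red(noisy) == flag_noisy_red(scaled) == 1


class TestRunQC:
    def _table(self, spectra):
        ids = [f"S{i:03d}" for i in range(len(spectra))]
        values = np.array([s.values for s in spectra])
        return SpectralTable(
            quantity=Quantity.RRS, ids=ids, grid=GRID.astype(int), values=values
        )

    def test_empty_table(self):
        t = SpectralTable(
            quantity=Quantity.RRS,
            ids=[],
            grid=GRID.astype(int),
            values=np.empty((0, GRID.size)),
        )
        results, ancillary = run_qc(t)
        assert results == [] and ancillary == []

    def test_non_rrs_table_rejected(self, smooth_spectrum):
        t = SpectralTable(
            quantity=Quantity.ES,
            ids=["a"],
            grid=GRID.astype(int),
            values=smooth_spectrum.values[None, :],
        )
        with pytest.raises(ValueError):
            run_qc(t)

    def test_deterministic_bit_for_bit(self, smooth_spectrum):
        t = self._table([smooth_spectrum] * 3)
        r1, a1 = run_qc(t)
        r2, a2 = run_qc(t)
        assert r1 == r2
        assert [vars(x) for x in a1] == [vars(x) for x in a2]

    def test_suspect_mapping_applied(self, smooth_spectrum):
        t = self._table([smooth_spectrum, smooth_spectrum])
        results, _ = run_qc(t, suspects={"S001": 1})
        assert results[0].suspect is None and results[0].flagged == 0
        assert results[1].suspect == 1 and results[1].flagged == 1

    def test_flag_counts_tally(self, smooth_spectrum):
        noisy = _with_alternating(smooth_spectrum, 750, 900, 0.3)
        t = self._table([smooth_spectrum, noisy])
        results, _ = run_qc(t)
        counts = flag_counts(results)
        assert counts["noisy_red"] == 1
        assert counts["flagged"] == 1

    def test_qc_spectrum_returns_both_outputs(self, smooth_spectrum):
        res, anc = qc_spectrum("x", smooth_spectrum)
        assert res.gloria_id == anc.gloria_id == "x"
        assert np.isfinite(anc.avw)
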