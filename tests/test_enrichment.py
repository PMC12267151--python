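import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pigtracer.enrichment import (
    CalibrationFailureError,
    DegenerateCalibrationError,
    EnrichmentCurve,
    baseline_correct,
    build_calibration,
    delta_to_ape,
    ratio_to_mpe,
)


class TestCalibration:
    def test_exact_linear_standards_recovered_to_machine_precision(self):
        # six standards spanning 0–2.5 MPE with a perfectly linear response
        slope, intercept = 2.0, 0.1
        mpe = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5])
        standards = [(m, (m - intercept) / slope) for m in mpe]
        cal = build_calibration(standards)
        assert cal.slope == pytest.approx(slope, abs=1e-12)
        assert cal.intercept == pytest.approx(intercept, abs=1e-12)
        assert cal.valid_range == (0.0, 2.5)
        assert cal.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert cal.n_standards == 6

    def test_identity_calibration(self):
        cal = build_calibration([(0.0, 0.0), (1.0, 1.0)])
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-15)

    def test_fewer_than_two_distinct_standards_rejected(self):
        with pytest.raises(DegenerateCalibrationError):
            build_calibration([(1.0, 0.5), (1.0, 0.6)])

    def test_negative_slope_rejected(self):
        with pytest.raises(CalibrationFailureError):
            build_calibration([(0.0, 1.0), (1.0, 0.5), (2.0, 0.1)])

    def test_noisy_slope_coverage_matches_t_distribution(self):
        # Monte-Carlo oracle: with 6 standards the residual SD has 4 df, so
        # the ±3·SE interval covers the true slope with probability
        # 1 − P(|t₄| > 3) ≈ 0.960 (not the ~0.997 of known-σ intervals)
        from scipy import stats

        rng = np.random.default_rng(2024)
        true_slope = 2.0
        mpe = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5])
        clean_ratio = mpe / true_slope
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            ratio = clean_ratio + 0.01 * rng.standard_normal(6)
            cal = build_calibration(list(zip(mpe, ratio)))
            sxx = np.sum((ratio - ratio.mean()) ** 2)
            se = cal.residual_sd / np.sqrt(sxx)
            hits += abs(cal.slope - true_slope) <= 3 * se
        expected = 1.0 - 2.0 * stats.t.sf(3.0, 4)
        assert abs(hits / n_rep - expected) < 0.02

    def test_ratio_to_mpe_identity_and_extrapolation_flag(self):
        cal = build_calibration([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])
        mpe, flags = ratio_to_mpe(0.8, cal)
        assert mpe == pytest.approx(0.8)
        assert flags == []
        mpe, flags = ratio_to_mpe(1.05, cal)  # predicts 2.1 > hi = 2.0
        assert mpe == pytest.approx(1.05)
        cal_hi = build_calibration([(0.1, 0.0), (2.0, 0.95)])
        mpe, flags = ratio_to_mpe(1.0, cal_hi)
        assert mpe > 2.0 and "extrapolated" in flags

    def test_strongly_negative_prediction_clamped(self):
        cal = build_calibration([(0.0, 0.1), (1.0, 0.6), (2.0, 1.1)])
        mpe, flags = ratio_to_mpe(-2.0, cal)
        assert mpe == 0.0
        assert "clamped_negative" in flags

    def test_round_trip_through_inverse_within_1e10(self):
        rng = np.random.default_rng(5)
        mpe = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5])
        ratio = 0.48 * mpe + 0.01 + 0.005 * rng.standard_normal(6)
        cal = build_calibration(list(zip(mpe, ratio)))
        for target in np.linspace(0.0, 2.5, 11):
            simulated_ratio = cal.inverse(target)
            back, _ = ratio_to_mpe(simulated_ratio, cal)
            assert back == pytest.approx(target, abs=1e-10)


class TestDeltaToApe:
    @given(st.floats(min_value=-900, max_value=2000))
    @settings(max_examples=50, deadline=None)
    def test_equal_deltas_give_zero(self, delta):
        assert delta_to_ape(delta, delta) == 0.0

    def test_hand_checked_value(self):
        # closed form at δ = +100 ‰ over a 0 ‰ basal with the VPDB ratio:
        # AF(100) − AF(0) = 0.0121488… − 0.0110566… = 0.00109216…
        assert delta_to_ape(100.0, 0.0) == pytest.approx(0.10922, abs=5e-5)

    def test_monotone_in_sample_delta(self):
        apes = [delta_to_ape(d, -10.0) for d in np.linspace(-50, 200, 30)]
        assert np.all(np.diff(apes) > 0)

    @pytest.mark.parametrize("bad", [-1000.0, -1500.0, float("nan")])
    def test_nonphysical_delta_rejected(self, bad):
        with pytest.raises(ValueError):
            delta_to_ape(bad, 0.0)


class TestBaselineCorrect:
    def _curve(self, values, times=(-15, 30, 60, 90, 120)):
        return EnrichmentCurve(
            animal_id="a1", analyte="Gln_m5", unit="MPE",
            times_min=np.array(times, float), values=np.array(values, float),
            basal=float(values[0]),
        )

    def test_constant_curve_becomes_zero(self):
        out = baseline_correct(self._curve([0.05] * 5))
        assert np.allclose(out.values, 0.0)
        assert out.basal == 0.0

    def test_basal_subtracted_from_peak(self):
        out = baseline_correct(self._curve([0.02, 0.5, 1.20, 0.8, 0.4]))
        assert out.values[2] == pytest.approx(1.18)

    def test_idempotent_and_grid_preserving(self):
        c = self._curve([0.02, 0.5, 1.20, 0.8, 0.4])
        once = baseline_correct(c)
        twice = baseline_correct(once)
        assert np.array_equal(once.values, twice.values)
        assert np.array_equal(once.times_min, c.times_min)

    def test_negative_values_flagged_not_dropped(self):
        out = baseline_correct(self._curve([0.05, 0.01, 0.5, 0.3, 0.2]))
        assert out.values[1] < 0
        assert "negative_enrichment" in out.flags

    def test_missing_basal_raises_with_animal_named(self):
        c = EnrichmentCurve(
            animal_id="pig-7", analyte="Glc_m6", unit="MPE",
            times_min=np.array([30.0, 60.0, 90.0, 120.0, 150.0]),
            values=np.ones(5),
        )
        with pytest.raises(ValueError, match="pig-7"):
            baseline_correct(c)
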