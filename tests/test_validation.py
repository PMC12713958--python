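import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from audiopvt import (
    DomainError,
    QuantizerModel,
    bland_altman,
    correct_measurements,
    one_sample_t,
    proportional_bias_regression,
    quantize,
    run_engine_validation,
    run_validation_experiment,
    systematic_error_moments,
)
from audiopvt.validation import PVT_BIAS_MARGIN_MS, PVT_SD_MARGIN_MS

from oracles import paired_stats_by_summation


class TestSystematicErrorMoments:
    @pytest.mark.parametrize(
        "delta,e,var",
        [(4, 1.5, 1.25), (1, 0.0, 0.0), (2, 0.5, 0.25)],
    )
    def test_enumerated_moments(self, delta, e, var):
        assert systematic_error_moments(delta) == (pytest.approx(e), pytest.approx(var))

    @pytest.mark.parametrize("delta", range(1, 13))
    def test_closed_form(self, delta):
        """Mean (delta-1)/2 and variance (delta^2-1)/12 of {0..delta-1}."""
        e, var = systematic_error_moments(delta)
        assert e == pytest.approx((delta - 1) / 2)
        assert var == pytest.approx((delta**2 - 1) / 12)

    @pytest.mark.parametrize("bad", [0, -1, 2.5])
    def test_invalid_interval(self, bad):
        with pytest.raises(DomainError):
            systematic_error_moments(bad)


class TestQuantize:
    def test_ceils_to_grid(self):
        assert quantize(301.0, QuantizerModel(4.0, 0.0)) == 304.0

    def test_on_grid_unchanged(self):
        assert quantize(304.0, QuantizerModel(4.0, 0.0)) == 304.0

    def test_phase_shifts_grid(self):
        assert quantize(301.0, QuantizerModel(4.0, 2.0)) == 302.0

    def test_offset_within_interval(self, rng):
        t = rng.uniform(0, 1000, 500)
        for phase in (0.0, 1.0, 3.5):
            m = quantize(t, QuantizerModel(4.0, phase))
            assert np.all(m - t >= -1e-9) and np.all(m - t < 4.0)

    def test_random_integer_phase_mean_offset(self, rng):
        """With per-trial integer phases the mean offset converges to E(se)."""
        t = rng.integers(300, 990, size=20000).astype(float)
        phases = rng.integers(0, 4, size=t.size)
        m = np.array([quantize(ti, QuantizerModel(4.0, float(p))) for ti, p in zip(t, phases)])
        offsets = m - t
        assert set(np.unique(offsets)) <= {0.0, 1.0, 2.0, 3.0}
        se = offsets.std(ddof=1) / np.sqrt(offsets.size)
        assert abs(offsets.mean() - 1.5) < 3 * se

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            quantize(-1.0, QuantizerModel(4.0, 0.0))


class TestCorrectMeasurements:
    def test_printed_bias_correction(self):
        """A 1.30 ms measured-vs-expected bias becomes -0.20 ms after removing
        the 1.5 ms expected quantization error of a 4 ms sampler."""
        expected = np.arange(300.0, 990.0, 10.0)
        measured = expected + 1.30
        corrected = correct_measurements(measured, 4)
        diff = corrected.values - expected
        assert diff.mean() == pytest.approx(-0.20)

    def test_unit_interval_is_identity(self, rng):
        measured = rng.uniform(300, 900, 50)
        corrected = correct_measurements(measured, 1)
        assert np.array_equal(corrected.values, measured)
        assert corrected.corrected_variance == pytest.approx(measured.var(ddof=1))

    def test_monte_carlo_recovers_true_mean(self, rng):
        true = rng.uniform(300, 900, 5000).round()
        offsets = rng.integers(0, 4, size=true.size)
        corrected = correct_measurements(true + offsets, 4)
        se = corrected.values.std(ddof=1) / np.sqrt(true.size)
        assert abs(corrected.corrected_mean - true.mean()) < 3 * se

    def test_variance_floor_warns(self):
        measured = np.array([500.0, 500.5, 500.2, 499.9])
        with pytest.warns(UserWarning, match="floored"):
            corrected = correct_measurements(measured, 4)
        assert corrected.corrected_variance == 0.0

    @given(
        st.lists(st.floats(min_value=0.0, max_value=2000.0), min_size=2, max_size=50),
        st.integers(min_value=1, max_value=8),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_correction_algebra(self, values, delta):
        """corrected mean + E(se) = measured mean; corrected variance +
        VAR(se) = measured variance whenever non-negative."""
        measured = np.asarray(values)
        e_se, var_se = systematic_error_moments(delta)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrected = correct_measurements(measured, delta)
        assert corrected.corrected_mean + e_se == pytest.approx(measured.mean(), abs=1e-9)
        sample_var = measured.var(ddof=1)
        if sample_var >= var_se:
            assert corrected.corrected_variance + var_se == pytest.approx(sample_var, rel=1e-9, abs=1e-9)
        else:
            assert corrected.corrected_variance == 0.0


class TestBlandAltman:
    def test_identical_series_degenerate(self):
        a = np.array([300.0, 400.0, 500.0, 600.0])
        rep = bland_altman(a, a)
        assert rep.mean_diff == 0.0
        assert (rep.loa_low, rep.loa_high) == (0.0, 0.0)
        assert not rep.t_defined

    def test_matches_direct_summation(self, rng):
        a = rng.uniform(300, 900, 20)
        b = a + rng.normal(0, 2, 20)
        rep = bland_altman(a, b)
        mean, sd, sem, t = paired_stats_by_summation(a, b)
        assert rep.mean_diff == pytest.approx(mean)
        assert rep.sd_diff == pytest.approx(sd)
        assert rep.sem == pytest.approx(sem)
        assert rep.t_statistic == pytest.approx(t)
        assert rep.loa_low == pytest.approx(mean - 1.96 * sd)
        assert rep.loa_high == pytest.approx(mean + 1.96 * sd)

    def test_matches_scipy_paired_t(self, rng):
        a = rng.uniform(300, 900, 40)
        b = a + rng.normal(1.0, 2.0, 40)
        rep = bland_altman(a, b)
        t, p = scipy.stats.ttest_rel(a, b)
        assert rep.t_statistic == pytest.approx(t)
        assert rep.p_value == pytest.approx(p)
        assert rep.df == 39

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            bland_altman(np.arange(5.0), np.arange(6.0))

    @given(st.lists(st.tuples(
        st.floats(min_value=0, max_value=1000),
        st.floats(min_value=0, max_value=1000),
    ), min_size=3, max_size=40))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_loa_midpoint_is_mean_diff(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        rep = bland_altman(a, b)
        assert 0.5 * (rep.loa_low + rep.loa_high) == pytest.approx(rep.mean_diff, abs=1e-9)


class TestProportionalBiasRegression:
    def test_constant_offset_has_zero_slope(self):
        a = np.arange(300.0, 400.0, 10.0)
        b = a + 5.0
        res = proportional_bias_regression(a, b)
        assert res.slope == pytest.approx(0.0, abs=1e-10)
        assert res.intercept == pytest.approx(-5.0)

    def test_recovers_constructed_proportional_bias(self, rng):
        a = rng.uniform(300, 900, 200)
        b = 1.002 * a + rng.normal(0, 0.3, 200)
        res = proportional_bias_regression(a, b)
        # d = a - b ~ -0.002 a; mean ~ 1.001 a, so slope ~ -0.002/1.001
        truth = -0.002 / 1.001
        assert res.slope_ci[0] <= truth <= res.slope_ci[1]
        assert res.slope_p < 0.05

    def test_no_bias_rarely_significant(self):
        """With no true slope, the regression stays non-significant in at
        least 90% of a pre-registered set of 20 seeds."""
        grid = np.arange(300.0, 991.0, 10.0)
        a = np.tile(grid, 15)[:1000]
        n_ns = 0
        for seed in range(20):
            b = a + np.random.default_rng(seed).normal(0.0, 0.9, a.size)
            if proportional_bias_regression(a, b).slope_p > 0.05:
                n_ns += 1
        assert n_ns >= 18

    def test_zero_variance_in_means_flagged(self):
        a = np.full(10, 500.0)
        res = proportional_bias_regression(a, a)
        assert not res.defined

    def test_matches_scipy_linregress(self, rng):
        a = rng.uniform(300, 900, 50)
        b = a + rng.normal(0, 1, 50)
        res = proportional_bias_regression(a, b)
        lr = scipy.stats.linregress(0.5 * (a + b), a - b)
        assert res.slope == pytest.approx(lr.slope)
        assert res.intercept == pytest.approx(lr.intercept)
        assert res.slope_p == pytest.approx(lr.pvalue)


class TestOneSampleT:
    def test_all_equal_to_nominal(self):
        t, df, p = one_sample_t(np.full(10, 500.0), 500.0)
        assert t == 0.0 and df == 9

    def test_hand_computed_small_sample(self):
        t, df, p = one_sample_t(np.array([1.0, 2.0, 3.0]), 0.0)
        assert t == pytest.approx(2.0 / (1.0 / math.sqrt(3.0)))
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2

    def test_matches_scipy(self, rng):
        x = rng.normal(504.0, 5.0, 100)
        t, df, p = one_sample_t(x, 500.0)
        ref = scipy.stats.ttest_1samp(x, 500.0)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_stimulus_prolongation_scale(self, rng):
        """A 1,000-sample series built with mean 504.3 and SD 4.9 against a
        500 ms nominal lands in the t-range implied by those summaries."""
        z = rng.normal(size=1000)
        z = (z - z.mean()) / z.std(ddof=1)
        x = 504.3 + 4.9 * z
        t, df, p = one_sample_t(x, 500.0)
        assert t == pytest.approx(4.3 / (4.9 / math.sqrt(1000.0)))
        lo = 4.25 / (4.95 / math.sqrt(1000.0))
        hi = 4.35 / (4.85 / math.sqrt(1000.0))
        assert lo <= t <= hi
        assert lo <= 27.4778 <= hi  # a printed t from such summaries is in-range
        assert p < 1e-4


class TestValidationExperiment:
    def test_zero_jitter_recorded_equals_expected(self):
        rep = run_validation_experiment(n_trials=1000, jitter_sd=0.0, seed=12)
        rve = rep.comparisons["recorded_vs_expected"]
        assert rve.mean_diff == 0.0
        assert rve.sd_diff == 0.0

    def test_measured_bias_near_e_se(self):
        rep = run_validation_experiment(n_trials=1000, seed=12)
        mve = rep.comparisons["measured_vs_expected"]
        assert abs(mve.mean_diff - 1.5) < 3 * mve.sem

    def test_correction_removes_quantization_bias(self):
        rep = run_validation_experiment(n_trials=1000, seed=12)
        cve = rep.comparisons["corrected_vs_expected"]
        assert abs(cve.mean_diff) < 3 * cve.sem

    def test_unit_interval_all_series_coincide(self):
        rep = run_validation_experiment(n_trials=200, sampling_interval=1, seed=3)
        for comp in rep.comparisons.values():
            assert comp.mean_diff == 0.0

    def test_bias_converges_to_e_se_at_large_n(self):
        rep = run_validation_experiment(n_trials=100000, seed=17)
        mve = rep.comparisons["measured_vs_expected"]
        assert abs(mve.mean_diff - 1.5) < 3 * mve.sem

    def test_raw_triples_schema(self, tmp_path):
        rep = run_validation_experiment(n_trials=100, seed=5)
        path = rep.to_csv(tmp_path / "raw.csv")
        header = path.read_text().splitlines()[0]
        assert header == "trial,expected_ms,recorded_ms,measured_ms,corrected_ms"
        assert len(rep.triples) == 100

    def test_five_comparisons_reported(self):
        rep = run_validation_experiment(n_trials=100, seed=5)
        assert list(rep.comparisons) == [
            "recorded_vs_expected",
            "measured_vs_expected",
            "corrected_vs_expected",
            "recorded_vs_measured",
            "recorded_vs_corrected",
        ]

    def test_jitter_widens_recorded_loa(self):
        rep = run_validation_experiment(n_trials=1000, jitter_sd=0.9, seed=21)
        rve = rep.comparisons["recorded_vs_expected"]
        half_width = 0.5 * (rve.loa_high - rve.loa_low)
        mc_se = 1.96 * 0.9 / math.sqrt(2 * (1000 - 1))
        assert abs(half_width - 1.96 * 0.9) < 3 * mc_se

    def test_seed_determinism(self):
        a = run_validation_experiment(n_trials=100, seed=9, jitter_sd=0.5)
        b = run_validation_experiment(n_trials=100, seed=9, jitter_sd=0.5)
        assert a.triples.equals(b.triples)


class TestEngineValidation:
    def test_engine_adds_no_bias(self):
        res = run_engine_validation(n_trials=200, seed=2)
        assert abs(res.bias) < 1e-9
        assert res.sd < 1e-9
        assert res.within_pvt_margins

    def test_margin_constants(self):
        assert PVT_BIAS_MARGIN_MS == 5.0
        assert PVT_SD_MARGIN_MS == 10.0
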