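import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronofish import (
    LocomotorSimConfig,
    PeakSet,
    RhythmEstimator,
    Series,
    estimate_amplitude,
    estimate_period,
    estimate_phase,
    find_extrema,
    g_factor,
    make_light_schedule,
    peak_weights,
    phase_difference,
    phase_to_ct,
    simulate_locomotor_cohort,
    split_ld_dd,
)
from chronofish.rhythm import periodogram
from oracles import circular_distance_h, dft_power_oracle


def series(values, dt_h=1.0):
    values = np.asarray(values, dtype=float)
    return Series(np.arange(values.size) * dt_h, values)


def peakset(peak_times, peak_heights=None, trough_times=(), trough_heights=None):
    peak_times = np.asarray(peak_times, dtype=float)
    trough_times = np.asarray(trough_times, dtype=float)
    if peak_heights is None:
        peak_heights = np.ones_like(peak_times)
    if trough_heights is None:
        trough_heights = np.zeros_like(trough_times)
    return PeakSet(peak_times, peak_heights, trough_times, trough_heights)


class TestFindExtrema:
    def test_alternating_sawtooth(self):
        ps = find_extrema(series([0, 1, 0, 1, 0]))
        np.testing.assert_allclose(ps.peak_times, [1.0, 3.0])
        np.testing.assert_allclose(ps.trough_times, [2.0])

    def test_monotone_series_has_no_extrema(self):
        ps = find_extrema(series([1, 2, 3, 4, 5]))
        assert ps.n_peaks == 0 and ps.trough_times.size == 0

    def test_plateau_yields_midpoint_extremum(self):
        ps = find_extrema(series([0, 1, 1, 0]))
        np.testing.assert_allclose(ps.peak_times, [1.5])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            find_extrema(series([1, 2]))

    def test_endpoints_never_extrema(self):
        ps = find_extrema(series([5, 1, 2, 1, 5]))
        assert 0.0 not in ps.peak_times and 4.0 not in ps.peak_times

    def test_min_prominence_prunes_ripple(self):
        v = np.array([0.0, 1.0, 0.5, 0.5 + 1e-9, 0.5 - 1e-9, 1.0, 0.0])
        with_ripple = find_extrema(series(v))
        pruned = find_extrema(series(v), min_prominence=1e-6)
        assert with_ripple.n_peaks == 3
        assert pruned.n_peaks == 2
        np.testing.assert_allclose(pruned.peak_times, [1.0, 5.0])


class TestEstimatePeriod:
    def test_even_spacing_any_weights(self):
        ps = peakset([0, 24, 48])
        assert estimate_period(ps, weights=[5, 1, 2]) == pytest.approx(24.0)

    def test_unweighted_mean_of_gaps(self):
        assert estimate_period(peakset([2, 26, 52]), weighted=False) == pytest.approx(25.0)

    def test_flanking_mean_gap_weights(self):
        # gaps 24 (weight (1+1)/2) and 26 (weight (1+3)/2)
        got = estimate_period(peakset([2, 26, 52]), weights=[1, 1, 3])
        assert got == pytest.approx((24 * 1 + 26 * 2) / 3)

    def test_fewer_than_two_peaks_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            estimate_period(peakset([10.0]))


class TestEstimatePhase:
    def test_exact_24h_peaks(self):
        assert estimate_phase(peakset([6, 30, 54]), 24.0) == pytest.approx(6.0)

    def test_circular_mean_across_midnight(self):
        assert estimate_phase(peakset([23, 25]), 24.0) == pytest.approx(0.0, abs=1e-9)

    def test_mean_direction_of_0_and_90_degrees(self):
        assert estimate_phase(peakset([0, 6]), 24.0) == pytest.approx(3.0)

    def test_antipodal_peaks_undefined(self):
        with pytest.raises(ValueError, match="resultant"):
            estimate_phase(peakset([0, 12]), 24.0)

    def test_ct_rescaling(self):
        assert phase_to_ct(13.0, 26.0) == pytest.approx(12.0)


class TestPeakWeightsAndAmplitude:
    def test_weights_are_height_minus_preceding_trough(self):
        ps = peakset(
            [10, 34], peak_heights=[1.6, 1.2], trough_times=[20], trough_heights=[0.4]
        )
        # first peak uses the following trough, second its preceding trough
        np.testing.assert_allclose(peak_weights(ps), [1.2, 0.8])

    def test_amplitude_is_half_peak_minus_trough(self):
        s = series(np.zeros(5))
        ps = peakset(
            [10, 30], peak_heights=[1.0, 1.6], trough_times=[20], trough_heights=[0.4]
        )
        got = estimate_amplitude(s, ps, selector="second_day")
        assert got == pytest.approx((1.6 - 0.4) / 2)

    def test_peak_without_preceding_trough_rejected(self):
        ps = peakset([30], peak_heights=[1.0])
        with pytest.raises(ValueError, match="trough"):
            estimate_amplitude(series(np.zeros(5)), ps, selector="second_day")

    def test_flat_series_propagates_no_peaks_error(self):
        flat = find_extrema(series(np.full(10, 1.0)))
        with pytest.raises(ValueError):
            estimate_amplitude(series(np.zeros(5)), flat, selector="second_day")


class TestGFactor:
    def test_pure_24h_cosine_scores_one(self, cosine_series):
        assert g_factor(cosine_series) >= 0.99

    def test_12h_cosine_scores_zero(self):
        t = np.arange(432) / 6.0
        assert g_factor(Series(t, np.cos(2 * np.pi * t / 12.0))) <= 0.01

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=-20.0, max_value=20.0),
    )
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(0)
        t = np.arange(300) / 6.0
        v = rng.gamma(2.0, size=300) + np.cos(2 * np.pi * t / 24)
        s = Series(t, v)
        g1 = g_factor(s)
        g2 = g_factor(Series(t, scale * v + offset))
        assert abs(g1 - g2) <= 1e-12

    def test_short_span_rejected(self):
        t = np.arange(100) / 6.0  # 16.5 h < 48 h
        with pytest.raises(ValueError, match="insufficient"):
            g_factor(Series(t, np.sin(t)))

    def test_periodogram_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(9)
        for n in (16, 100, 256):
            x = rng.normal(size=n)
            freqs, power = periodogram(x, dt_h=1 / 6.0)
            of, op = dft_power_oracle(x, 1 / 6.0)
            np.testing.assert_allclose(freqs, of, atol=1e-12)
            np.testing.assert_allclose(power, op, atol=1e-9 * max(1, op.max()))

    def test_lombscargle_agrees_on_uniform_cosine(self, cosine_series):
        assert g_factor(cosine_series, method="lombscargle") >= 0.99


class TestSplitLdDd:
    def test_first_peak_after_boundary_closes_ld(self):
        ps = peakset([100, 109, 130])
        ld, dd = split_ld_dd(ps, boundary_h=108.0)
        np.testing.assert_allclose(ld.peak_times, [100, 109])
        np.testing.assert_allclose(dd.peak_times, [130])

    def test_all_peaks_before_boundary_leaves_dd_empty(self):
        ld, dd = split_ld_dd(peakset([50, 74, 98]), boundary_h=108.0)
        assert ld.n_peaks == 3 and dd.n_peaks == 0

    def test_empty_peakset_splits_to_empty(self):
        ld, dd = split_ld_dd(peakset([]), boundary_h=108.0)
        assert ld.n_peaks == 0 and dd.n_peaks == 0


class TestPhaseDifference:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(2.0, 9.2, 7.2), (23.0, 1.0, 2.0), (0.0, 12.0, 12.0), (9.2, 2.0, -7.2)],
    )
    def test_signed_minimal_difference(self, a, b, expected):
        assert phase_difference(a, b) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.floats(min_value=0, max_value=24, exclude_max=True),
        st.floats(min_value=0, max_value=24, exclude_max=True),
    )
    def test_range_and_consistency(self, a, b):
        d = phase_difference(a, b)
        assert -12.0 < d <= 12.0
        assert circular_distance_h((a + d) % 24.0, b % 24.0) <= 1e-9


class TestRhythmEstimatorRecovery:
    @pytest.mark.parametrize("period", [22.0, 24.0, 26.0, 27.0, 30.0])
    def test_noiseless_cohort_recovers_truth_within_0p1h(self, period):
        """Noiseless subjects: period and phase recovered to within 0.1 h."""
        sch = make_light_schedule("DIMDIM", 6)
        cfg = LocomotorSimConfig(
            period_h=period,
            n_days=6,
            phase_jitter_sd_h=0.0,
            period_sd_h=0.0,
            noise_dispersion=0.0,
            seed=0,
        )
        traces = simulate_locomotor_cohort(cfg, sch, 24)
        for tr in traces[:3]:  # cohort is identical without between-subject spread
            est = RhythmEstimator().fit(tr)
            assert est.period_h_ == pytest.approx(tr.truth["period_h"], abs=0.1)
            assert (
                circular_distance_h(est.phase_h_, tr.truth["phase_h"], est.period_h_)
                <= 0.1
            )

    def test_estimator_exposes_sklearn_params(self):
        est = RhythmEstimator(weighted=False)
        assert est.get_params()["weighted"] is False
        est.set_params(gap_weight_rule="left")
        assert est.gap_weight_rule == "left"
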