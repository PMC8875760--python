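import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronofish import (
    ActogramSmoother,
    MeanNormalizer,
    Series,
    loess,
    moving_average,
    moving_percentile,
    normalize_by_mean,
    smooth_actogram,
    standardize_well,
)
from oracles import loess_oracle, moving_mean_oracle, moving_percentile_oracle


def series(values, dt_h=1.0):
    values = np.asarray(values, dtype=float)
    return Series(np.arange(values.size) * dt_h, values)


positive_arrays = st.lists(
    st.floats(min_value=0.01, max_value=100.0), min_size=2, max_size=40
).map(np.array)


class TestNormalizeByMean:
    def test_simple_arithmetic(self):
        np.testing.assert_allclose(
            normalize_by_mean(series([1, 2, 3])).values, [0.5, 1.0, 1.5]
        )

    def test_constant_becomes_ones(self):
        np.testing.assert_allclose(normalize_by_mean(series([7, 7, 7, 7])).values, 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero-activity"):
            normalize_by_mean(series([0, 0, 0]))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(positive_arrays)
    def test_idempotent(self, values):
        once = normalize_by_mean(series(values))
        twice = normalize_by_mean(once)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)
        assert once.values.mean() == pytest.approx(1.0)


class TestStandardizeWell:
    def test_simple_case_sample_sd(self):
        np.testing.assert_allclose(
            standardize_well(series([1, 2, 3])).values, [-1.0, 0.0, 1.0], atol=1e-12
        )

    def test_constant_well_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_well(series([4, 4, 4]))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        positive_arrays.filter(lambda v: np.std(v) > 1e-6),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_affine_invariance(self, values, a, b):
        z1 = standardize_well(series(values)).values
        z2 = standardize_well(series(a * values + b)).values
        np.testing.assert_allclose(z1, z2, atol=1e-8)


class TestMovingAverage:
    def test_constant_smooth_unchanged_detrend_zero(self):
        s = series(np.full(30, 3.0))
        np.testing.assert_allclose(moving_average(s, 9.0, "smooth").values, 3.0)
        np.testing.assert_allclose(
            moving_average(s, 9.0, "detrend").values, 0.0, atol=1e-12
        )

    def test_detrend_then_smooth_recovers_cosine(self):
        """29 h detrend + 9 h smooth isolates a 24-h cosine from a linear ramp."""
        t = np.arange(0, 120, 1 / 6.0)
        cos = np.cos(2 * np.pi * t / 24.0)
        s = Series(t, cos + 0.05 * t)
        out = moving_average(
            moving_average(s, 29.0, "detrend"), 9.0, "smooth"
        ).values
        interior = slice(15 * 6, -15 * 6)
        r = np.corrcoef(out[interior], cos[interior])[0, 1]
        assert r > 0.99

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            moving_average(series([1, 2, 3, 4]), 10.0, "smooth")

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for n in (17, 100, 500):
            s = series(rng.normal(size=n))
            k = 5
            got = moving_average(s, 2 * k * s.dt_h, "smooth").values
            np.testing.assert_allclose(got, moving_mean_oracle(s.values, k), atol=1e-12)


class TestMovingPercentile:
    def test_full_window_percentile_rule(self):
        # 75th percentile of [0,1,2,3,4] under linear rank interpolation
        s = series([0, 1, 2, 3, 4])
        assert moving_percentile(s, 75, half_window_points=2).values[2] == 3.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        s = series(rng.normal(size=301))
        for k in (1, 7, 20):
            got = moving_percentile(s, 75, half_window_points=k).values
            np.testing.assert_allclose(
                got, moving_percentile_oracle(s.values, k, 75), atol=1e-12
            )


class TestLoess:
    def test_linear_input_is_fixed_point(self):
        s = series(2.0 + 0.5 * np.arange(40.0))
        out = loess(s, half_window_points=8, mode="smooth").values
        np.testing.assert_allclose(out, s.values, rtol=1e-9)

    def test_constant_detrend_is_zero(self):
        s = series(np.full(25, 5.0))
        np.testing.assert_allclose(
            loess(s, half_window_points=5, mode="detrend").values, 0.0, atol=1e-12
        )

    def test_smoothing_reduces_noise_rmse(self):
        rng = np.random.default_rng(7)
        t = np.arange(432) / 6.0
        truth = np.cos(2 * np.pi * t / 24.0)
        noisy = truth + rng.normal(0, 0.5, t.size)
        sm = loess(Series(t, noisy), half_window_points=30, mode="smooth").values
        assert np.sqrt(np.mean((sm - truth) ** 2)) < np.sqrt(
            np.mean((noisy - truth) ** 2)
        )

    def test_too_narrow_window_rejected(self):
        with pytest.raises(ValueError, match="narrow"):
            loess(series([1, 2, 3, 4]), half_window_points=0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for n, k in ((50, 4), (203, 11), (500, 25)):
            s = series(rng.normal(size=n), dt_h=1 / 6.0)
            got = loess(s, half_window_points=k, mode="smooth").values
            np.testing.assert_allclose(
                got, loess_oracle(s.times, s.values, k), atol=1e-9
            )


class TestSmoothActogram:
    def test_default_windows_are_20_and_50_points_at_10min_bins(self):
        rng = np.random.default_rng(3)
        s = series(rng.gamma(2.0, size=432), dt_h=1 / 6.0)
        composed = loess(
            moving_percentile(s, 75, half_window_points=20),
            half_window_points=50,
            mode="smooth",
        )
        np.testing.assert_allclose(
            smooth_actogram(s).values, composed.values, atol=1e-12
        )

    def test_constant_series_unchanged(self):
        s = series(np.full(432, 2.0), dt_h=1 / 6.0)
        np.testing.assert_allclose(smooth_actogram(s).values, 2.0)

    def test_short_series_rejected(self):
        s = series(np.ones(50), dt_h=1 / 6.0)
        with pytest.raises(ValueError, match="shorter"):
            smooth_actogram(s)


class TestOperatorProperties:
    """Shared smoothing-operator invariances."""

    @pytest.mark.parametrize(
        "op",
        [
            lambda s: moving_average(s, 4.0, "smooth"),
            lambda s: loess(s, half_window_points=4, mode="smooth"),
        ],
        ids=["moving_average", "loess"],
    )
    def test_smooth_commutes_with_adding_constant(self, op):
        rng = np.random.default_rng(4)
        s = series(rng.normal(size=60))
        shifted = op(series(s.values + 3.5)).values
        np.testing.assert_allclose(shifted, op(s).values + 3.5, atol=1e-9)

    @pytest.mark.parametrize(
        "op",
        [
            lambda s: moving_average(s, 4.0, "detrend"),
            lambda s: loess(s, half_window_points=4, mode="detrend"),
        ],
        ids=["moving_average", "loess"],
    )
    def test_detrend_annihilates_constants(self, op):
        np.testing.assert_allclose(op(series(np.full(40, 9.0))).values, 0.0, atol=1e-9)

    def test_translation_equivariance_in_time(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=80)
        a = Series(np.arange(80.0), v)
        b = Series(np.arange(80.0) + 13.0, v)
        np.testing.assert_allclose(
            moving_average(a, 6.0, "smooth").values,
            moving_average(b, 6.0, "smooth").values,
            atol=1e-12,
        )
        np.testing.assert_allclose(
            loess(a, half_window_points=3).values,
            loess(b, half_window_points=3).values,
            atol=1e-9,
        )


class TestTransformers:
    def test_mean_normalizer_rows_have_unit_mean(self):
        rng = np.random.default_rng(6)
        X = rng.gamma(2.0, size=(5, 100))
        out = MeanNormalizer().fit_transform(X)
        np.testing.assert_allclose(out.mean(axis=1), 1.0)

    def test_actogram_smoother_matches_function(self):
        rng = np.random.default_rng(8)
        X = rng.gamma(2.0, size=(3, 432))
        out = ActogramSmoother(bin_min=10.0).fit_transform(X)
        for row_in, row_out in zip(X, out):
            expected = smooth_actogram(series(row_in, dt_h=1 / 6.0)).values
            np.testing.assert_allclose(row_out, expected, atol=1e-12)

    def test_transformers_expose_sklearn_params(self):
        sm = ActogramSmoother(loess_half_h=5.0)
        assert sm.get_params()["loess_half_h"] == 5.0
        sm.set_params(q=60.0)
        assert sm.q == 60.0
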