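"""Normalization, detrending, and smoothing of activity and bioluminescence.

The locomotor pipeline divides each subject's trace by its mean and smooths
with a LOESS-smoothed running 75th-percentile curve (half-windows 3.33 h and
8.33 h; exactly 20 and 50 sliding points each side at 10-min bins).  The
bioluminescence pipeline standardizes each well to zero mean / unit SD and
then detrends and smooths with either centered moving averages (29 h and 9 h
full windows) or LOESS (44 h and 22 h full windows), depending on the
experiment.

Conventions pinned here so every result is reproducible:

* Windows truncate at the series boundaries — no padding or reflection.
* LOESS is locally weighted degree-1 regression with a tricube kernel and no
  robustness iterations.  Tricube distances are scaled by the half-window
  plus one sample spacing, so the outermost sliding point still carries
  positive weight.
* Percentiles use linear interpolation between closest ranks.
* Standard deviations are sample SDs (ddof=1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ActivityTrace, LumTrace, Series

__all__ = [
    "normalize_by_mean",
    "standardize_well",
    "moving_average",
    "moving_percentile",
    "loess",
    "smooth_actogram",
    "MeanNormalizer",
    "ActogramSmoother",
]

#: Default half-window widths (hours) of the actogram smoother: 3.33 h for the
#: running 75th percentile and 8.33 h for the LOESS stage (20 and 50 sliding
#: points each side at 10-min bins).
PERCENTILE_HALF_WINDOW_H = 10.0 / 3.0
LOESS_HALF_WINDOW_H = 25.0 / 3.0


def _coerce_series(x) -> Series:
    if isinstance(x, Series):
        return x
    if isinstance(x, (ActivityTrace, LumTrace)):
        return x.to_series()
    raise TypeError(f"expected Series, ActivityTrace or LumTrace, got {type(x).__name__}")


def normalize_by_mean(trace: ActivityTrace | Series) -> Series:
    """Divide an activity series by its mean, giving a mean-1 series."""
    s = _coerce_series(trace)
    m = s.values.mean()
    if m <= 0:
        raise ValueError("cannot normalize zero-activity trace")
    return s.with_values(s.values / m)


def standardize_well(trace: LumTrace | Series) -> Series:
    """Standardize one well's counts: subtract mean, divide by sample SD."""
    s = _coerce_series(trace)
    sd = s.values.std(ddof=1)
    if sd <= 0:
        raise ValueError(f"constant well cannot be standardized (SD = 0)")
    return s.with_values((s.values - s.values.mean()) / sd)


def _half_window_points(half_h: float | None, half_points: int | None, dt_h: float) -> int:
    if (half_h is None) == (half_points is None):
        raise ValueError("give exactly one of a half-window in hours or in points")
    if half_points is not None:
        k = int(half_points)
    else:
        if half_h <= 0:
            raise ValueError("half-window must be positive")
        k = int(round(half_h / dt_h))
    return k


def moving_average(
    series: Series,
    window_h: float,
    mode: str = "smooth",
    width: str = "full",
) -> Series:
    """Centered moving mean (``smooth``) or its residual (``detrend``).

    ``window_h`` is the full window width by default (a 9 h window averages
    ±4.5 h around each point); pass ``width="half"`` to give the half-window
    instead.  Windows are truncated at the series boundaries.
    """
    if mode not in ("smooth", "detrend"):
        raise ValueError("mode must be 'smooth' or 'detrend'")
    if width not in ("full", "half"):
        raise ValueError("width must be 'full' or 'half'")
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    half_h = window_h / 2.0 if width == "full" else float(window_h)
    if 2 * half_h > series.span_h + 1e-9:
        raise ValueError("window longer than series span")
    k = int(np.floor(half_h / series.dt_h + 1e-9))
    sm = (
        pd.Series(series.values)
        .rolling(window=2 * k + 1, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return series.with_values(sm if mode == "smooth" else series.values - sm)


def moving_percentile(
    series: Series,
    q: float = 75.0,
    half_window_h: float | None = None,
    half_window_points: int | None = None,
) -> Series:
    """Centered running percentile with boundary-truncated windows."""
    if not 0 <= q <= 100:
        raise ValueError("q must be in [0, 100]")
    k = _half_window_points(half_window_h, half_window_points, series.dt_h)
    if k < 1:
        raise ValueError("window too narrow: must cover at least 1 point each side")
    v = series.values
    n = v.size
    out = np.empty(n)
    if n >= 2 * k + 1:
        windows = sliding_window_view(v, 2 * k + 1)
        out[k : n - k] = np.percentile(windows, q, axis=1)
    for i in list(range(min(k, n))) + list(range(max(n - k, 0), n)):
        out[i] = np.percentile(v[max(0, i - k) : min(n, i + k + 1)], q)
    return series.with_values(out)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _loess_fit_at(t: np.ndarray, v: np.ndarray, i: int, k: int, scale: float) -> float:
    """Weighted degree-1 local fit evaluated at point ``i`` (truncated window)."""
    lo, hi = max(0, i - k), min(t.size, i + k + 1)
    x = t[lo:hi] - t[i]
    y = v[lo:hi]
    w = _tricube(x / scale)
    sw = w.sum()
    swx = (w * x).sum()
    swx2 = (w * x * x).sum()
    swy = (w * y).sum()
    swxy = (w * x * y).sum()
    denom = sw * swx2 - swx * swx
    if denom <= 0:
        # Window degenerate to a single weighted point: fall back to the mean.
        return swy / sw
    return (swx2 * swy - swx * swxy) / denom


def loess(
    series: Series,
    half_window_h: float | None = None,
    half_window_points: int | None = None,
    mode: str = "smooth",
) -> Series:
    """LOESS (tricube, degree 1, no robustness passes) smooth or detrend.

    The fitted curve at an interior point reduces to a tricube-weighted
    moving average (the symmetric window makes the slope term orthogonal),
    which is used as a fast path; boundary points get explicit local fits on
    their truncated windows.
    """
    if mode not in ("smooth", "detrend"):
        raise ValueError("mode must be 'smooth' or 'detrend'")
    k = _half_window_points(half_window_h, half_window_points, series.dt_h)
    if 2 * k + 1 < 3:
        raise ValueError("window too narrow: LOESS needs >= 3 points per window")
    t, v = series.times, series.values
    n = v.size
    scale = (k + 1) * series.dt_h
    out = np.empty(n)
    if n >= 2 * k + 1:
        offs = np.arange(-k, k + 1) * series.dt_h
        kern = _tricube(offs / scale)
        kern = kern / kern.sum()
        out[k : n - k] = np.convolve(v, kern[::-1], mode="valid")
    for i in list(range(min(k, n))) + list(range(max(n - k, 0), n)):
        out[i] = _loess_fit_at(t, v, i, k, scale)
    return series.with_values(out if mode == "smooth" else v - out)


def smooth_actogram(
    series: Series,
    percentile_half_h: float = PERCENTILE_HALF_WINDOW_H,
    loess_half_h: float = LOESS_HALF_WINDOW_H,
    q: float = 75.0,
) -> Series:
    """Smooth a mean-normalized actogram: running 75th percentile, then LOESS.

    At 10-min bins the defaults give exactly 20 and 50 sliding points on each
    side of the centre bin for the two stages.
    """
    k1 = _half_window_points(percentile_half_h, None, series.dt_h)
    k2 = _half_window_points(loess_half_h, None, series.dt_h)
    if series.values.size < 2 * max(k1, k2) + 1:
        raise ValueError("series shorter than one full smoothing window")
    stage1 = moving_percentile(series, q=q, half_window_points=k1)
    return loess(stage1, half_window_points=k2, mode="smooth")


# ---------------------------------------------------------------------------
# sklearn-style transformers over subject × bin matrices
# ---------------------------------------------------------------------------


class MeanNormalizer(BaseEstimator, TransformerMixin):
    """Row-wise mean normalization of a subjects × bins activity matrix."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-d subjects × bins matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        means = X.mean(axis=1, keepdims=True)
        if np.any(means <= 0):
            bad = np.flatnonzero(means.ravel() <= 0).tolist()
            raise ValueError(f"cannot normalize zero-activity trace(s) at rows {bad}")
        return X / means


class ActogramSmoother(BaseEstimator, TransformerMixin):
    """Row-wise percentile + LOESS actogram smoothing of an activity matrix.

    Parameters mirror :func:`smooth_actogram`; ``bin_min`` sets the uniform
    bin width used to convert half-window hours into sliding points.
    """

    def __init__(
        self,
        bin_min: float = 10.0,
        percentile_half_h: float = PERCENTILE_HALF_WINDOW_H,
        loess_half_h: float = LOESS_HALF_WINDOW_H,
        q: float = 75.0,
    ):
        self.bin_min = bin_min
        self.percentile_half_h = percentile_half_h
        self.loess_half_h = loess_half_h
        self.q = q

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-d subjects × bins matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        times = np.arange(X.shape[1]) * (self.bin_min / 60.0)
        out = np.empty_like(X)
        for i, row in enumerate(X):
            out[i] = smooth_actogram(
                Series(times, row),
                percentile_half_h=self.percentile_half_h,
                loess_half_h=self.loess_half_h,
                q=self.q,
            ).values
        return out
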