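"""Period, phase, amplitude, and rhythmicity estimation from smoothed curves.

Peaks (local maxima) and troughs (local minima) of the normalized smoothed
curve carry the rhythm information:

* **Period** is the (amplitude-weighted) mean time difference between
  consecutive peaks.
* **Phase** is the (amplitude-weighted) circular mean direction of peak
  times relative to the estimated period, reported both on the subject's own
  period circle and rescaled to the 24-h circadian clock.
* **Amplitude** is half the difference in normalized activity between a
  selected peak (by default, the peak of the 2nd day of tracking) and the
  preceding trough.
* The **G-factor** scores 24-h rhythmicity as the ratio of periodogram power
  at the frequency closest to 1/24 h⁻¹ to the summed power of all positive
  frequencies (DC excluded); values near 1 indicate a clean circadian
  rhythm, values near 0 arrhythmicity.

Peak weights are proportional to peak amplitude (peak height minus preceding
trough height) because high-amplitude peaks are less noise-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lombscargle
from sklearn.base import BaseEstimator

from .containers import ActivityTrace, Series
from .preprocess import (
    LOESS_HALF_WINDOW_H,
    PERCENTILE_HALF_WINDOW_H,
    normalize_by_mean,
    smooth_actogram,
)

__all__ = [
    "PeakSet",
    "RhythmEstimate",
    "find_extrema",
    "peak_weights",
    "estimate_period",
    "estimate_phase",
    "phase_to_ct",
    "estimate_amplitude",
    "g_factor",
    "periodogram",
    "split_ld_dd",
    "phase_difference",
    "RhythmEstimator",
]

logger = logging.getLogger(__name__)


@dataclass
class PeakSet:
    """Ordered extrema of a smoothed curve (times in hours)."""

    peak_times: np.ndarray
    peak_heights: np.ndarray
    trough_times: np.ndarray
    trough_heights: np.ndarray

    def __post_init__(self) -> None:
        for name in ("peak_times", "peak_heights", "trough_times", "trough_heights"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.peak_times.size != self.peak_heights.size:
            raise ValueError("peak times/heights length mismatch")
        if self.trough_times.size != self.trough_heights.size:
            raise ValueError("trough times/heights length mismatch")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)


@dataclass
class RhythmEstimate:
    """Per-subject (or per-well) rhythm parameters."""

    period_h: float
    phase_h: float
    phase_ct_h: float
    amplitude: float
    g_factor: float
    n_peaks: int


def _compress_plateaus(times: np.ndarray, values: np.ndarray):
    """Collapse runs of equal consecutive values to their midpoint."""
    change = np.flatnonzero(np.diff(values) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [values.size - 1]))
    t = (times[starts] + times[ends]) / 2.0
    v = values[starts]
    return t, v


def find_extrema(series: Series, min_prominence: float = 0.0) -> PeakSet:
    """Interior strict local maxima and minima of a (smoothed) series.

    Plateaus of equal values yield a single extremum at the plateau midpoint;
    series endpoints are never extrema.  Alternation is enforced: of two
    consecutive peaks with no trough between them the lower is discarded
    (symmetrically for troughs).  When ``min_prominence`` > 0, adjacent
    peak/trough pairs whose height difference falls below it are removed
    (smallest first), suppressing ripple-scale extrema in near-flat regions.
    """
    if series.values.size < 3:
        raise ValueError("need at least 3 points to find extrema")
    t, v = _compress_plateaus(series.times, series.values)
    if t.size < 3:
        return PeakSet(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    d = np.sign(np.diff(v))
    interior = np.arange(1, t.size - 1)
    is_peak = (d[:-1] > 0) & (d[1:] < 0)
    is_trough = (d[:-1] < 0) & (d[1:] > 0)

    # Merge chronologically and enforce peak/trough alternation.
    events = [(t[i], v[i], +1) for i in interior[is_peak]]
    events += [(t[i], v[i], -1) for i in interior[is_trough]]
    events.sort()
    kept: list[tuple[float, float, int]] = []
    for ev in events:
        if kept and kept[-1][2] == ev[2]:
            prev = kept[-1]
            better = ev[1] > prev[1] if ev[2] == +1 else ev[1] < prev[1]
            if better:
                kept[-1] = ev
        else:
            kept.append(ev)
    # Prune low-prominence adjacent pairs; removing an adjacent (peak,
    # trough) pair preserves alternation.
    while min_prominence > 0 and len(kept) >= 2:
        diffs = [abs(kept[i + 1][1] - kept[i][1]) for i in range(len(kept) - 1)]
        i = int(np.argmin(diffs))
        if diffs[i] >= min_prominence:
            break
        del kept[i : i + 2]
    peaks = [(tt, vv) for tt, vv, kind in kept if kind == +1]
    troughs = [(tt, vv) for tt, vv, kind in kept if kind == -1]
    return PeakSet(
        peak_times=np.array([p[0] for p in peaks]),
        peak_heights=np.array([p[1] for p in peaks]),
        trough_times=np.array([p[0] for p in troughs]),
        trough_heights=np.array([p[1] for p in troughs]),
    )


def peak_weights(peaks: PeakSet) -> np.ndarray:
    """Weight per peak, proportional to its amplitude.

    A peak's amplitude is its height minus the preceding trough height; the
    first peak, lacking a preceding trough, uses the following trough.  With
    no troughs at all, peaks are weighted equally.
    """
    if peaks.n_peaks == 0:
        return np.empty(0)
    if peaks.trough_times.size == 0:
        return np.ones(peaks.n_peaks)
    w = np.empty(peaks.n_peaks)
    for i, (pt, ph) in enumerate(zip(peaks.peak_times, peaks.peak_heights)):
        before = np.flatnonzero(peaks.trough_times < pt)
        if before.size:
            ref = peaks.trough_heights[before[-1]]
        else:
            after = np.flatnonzero(peaks.trough_times > pt)
            ref = peaks.trough_heights[after[0]]
        w[i] = max(ph - ref, 0.0)
    if not np.any(w > 0):
        w = np.ones(peaks.n_peaks)
    return w


def estimate_period(
    peaks: PeakSet,
    weighted: bool = True,
    weights: np.ndarray | None = None,
    gap_weight_rule: str = "mean",
) -> float:
    """Mean (or amplitude-weighted mean) gap between consecutive peaks, hours.

    Weights attach to peaks; a gap's weight is derived from its two flanking
    peaks by ``gap_weight_rule``: ``mean`` (default), ``left``, or ``right``.
    """
    if peaks.n_peaks < 2:
        raise ValueError("period undefined: need at least 2 peaks")
    gaps = np.diff(peaks.peak_times)
    if not weighted:
        return float(gaps.mean())
    w = peak_weights(peaks) if weights is None else np.asarray(weights, dtype=float)
    if w.size != peaks.n_peaks:
        raise ValueError("one weight per peak required")
    if gap_weight_rule == "mean":
        gw = (w[:-1] + w[1:]) / 2.0
    elif gap_weight_rule == "left":
        gw = w[:-1]
    elif gap_weight_rule == "right":
        gw = w[1:]
    else:
        raise ValueError("gap_weight_rule must be 'mean', 'left' or 'right'")
    if gw.sum() <= 0:
        return float(gaps.mean())
    return float(np.average(gaps, weights=gw))


def estimate_phase(
    peaks: PeakSet,
    period_h: float,
    weighted: bool = True,
    weights: np.ndarray | None = None,
) -> float:
    """Circular mean direction of peak times on the period circle, hours.

    Peak times are mapped to angles θᵢ = 2π·(tᵢ mod P)/P and averaged as
    vectors (optionally amplitude-weighted); the mean direction is mapped
    back to hours in [0, P).
    """
    if peaks.n_peaks < 1:
        raise ValueError("phase undefined: need at least 1 peak")
    if period_h <= 0:
        raise ValueError("period_h must be positive")
    theta = 2.0 * np.pi * np.mod(peaks.peak_times, period_h) / period_h
    if weighted:
        w = peak_weights(peaks) if weights is None else np.asarray(weights, dtype=float)
    else:
        w = np.ones(peaks.n_peaks)
    if w.sum() <= 0:
        raise ValueError("phase undefined: nonpositive total weight")
    s = float(np.sum(w * np.sin(theta)))
    c = float(np.sum(w * np.cos(theta)))
    if np.hypot(s, c) / w.sum() < 1e-12:
        raise ValueError("phase undefined: zero resultant length")
    phase = float(np.mod(period_h / (2.0 * np.pi) * np.arctan2(s, c), period_h))
    if period_h - phase < 1e-9:  # float wrap: a hair below P is phase 0
        phase = 0.0
    return phase


def phase_to_ct(phase_h: float, period_h: float, circle_h: float = 24.0) -> float:
    """Rescale a phase from the subject's period circle to the 24-h CT clock."""
    return float(np.mod(phase_h * circle_h / period_h, circle_h))


def estimate_amplitude(
    series: Series,
    peaks: PeakSet,
    selector: str = "second_day",
    index: int | None = None,
) -> float:
    """Half the height difference between a selected peak and its preceding trough.

    ``selector="second_day"`` picks the highest peak with time in [24, 48) h;
    ``selector="explicit_index"`` uses ``index`` into the peak list.
    """
    if peaks.n_peaks == 0:
        raise ValueError("no peaks: amplitude undefined")
    if selector == "second_day":
        in_day2 = np.flatnonzero((peaks.peak_times >= 24.0) & (peaks.peak_times < 48.0))
        if in_day2.size == 0:
            raise ValueError("no peak in the 2nd day of tracking")
        i = int(in_day2[np.argmax(peaks.peak_heights[in_day2])])
    elif selector == "explicit_index":
        if index is None:
            raise ValueError("explicit_index selector requires index")
        i = int(index)
        if not 0 <= i < peaks.n_peaks:
            raise ValueError("peak index out of range")
    else:
        raise ValueError("selector must be 'second_day' or 'explicit_index'")
    pt, ph = peaks.peak_times[i], peaks.peak_heights[i]
    before = np.flatnonzero(peaks.trough_times < pt)
    if before.size == 0:
        raise ValueError("selected peak has no preceding trough")
    return float((ph - peaks.trough_heights[before[-1]]) / 2.0)


def periodogram(values: np.ndarray, dt_h: float):
    """DFT periodogram of a mean-subtracted series.

    Returns ``(freqs, power)`` over the positive frequencies up to Nyquist
    (DC excluded); ``power[k] = |Σ x_j exp(-2πi f_k t_j)|²``.
    """
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=dt_h)
    return freqs[1:], np.abs(spec[1:]) ** 2


def g_factor(series: Series, target_period_h: float = 24.0, method: str = "dft") -> float:
    """Rhythmicity score: periodogram power at the target period over total power.

    The numerator is the power at the positive frequency bin nearest
    1/``target_period_h``; the denominator sums power over all positive
    frequencies (DC excluded).  The score is invariant to adding a constant
    and to positive rescaling of the series.  ``method="lombscargle"``
    evaluates the same frequency grid with a Lomb–Scargle periodogram, for
    irregularly usable input; the default plain DFT suits the uniformly
    sampled recordings here.
    """
    if series.span_h < 2.0 * target_period_h - 1e-9:
        raise ValueError("insufficient data for G-factor: span < 2 target periods")
    if method == "dft":
        freqs, power = periodogram(series.values, series.dt_h)
    elif method == "lombscargle":
        freqs = np.fft.rfftfreq(series.values.size, d=series.dt_h)[1:]
        x = series.values - series.values.mean()
        power = lombscargle(series.times, x, 2.0 * np.pi * freqs)
    else:
        raise ValueError("method must be 'dft' or 'lombscargle'")
    total = power.sum()
    if total <= 0:
        raise ValueError("zero-variance series: G-factor undefined")
    k = int(np.argmin(np.abs(freqs - 1.0 / target_period_h)))
    logger.debug(
        "G-factor frequency bin %d (%.5f cycles/h, target %.5f)",
        k + 1,
        freqs[k],
        1.0 / target_period_h,
    )
    return float(power[k] / total)


def trim_peakset(peaks: PeakSet, t_min: float, t_max: float) -> PeakSet:
    """Drop extrema outside ``[t_min, t_max]`` (e.g. the smoothing edge regions)."""
    kp = (peaks.peak_times >= t_min) & (peaks.peak_times <= t_max)
    kt = (peaks.trough_times >= t_min) & (peaks.trough_times <= t_max)
    return PeakSet(
        peaks.peak_times[kp],
        peaks.peak_heights[kp],
        peaks.trough_times[kt],
        peaks.trough_heights[kt],
    )


def split_ld_dd(peaks: PeakSet, boundary_h: float = 108.0) -> tuple[PeakSet, PeakSet]:
    """Split extrema into LD and DD sets at the last-light-period mark.

    The last peak counted as LD is the first one strictly after
    ``boundary_h``; all later peaks are DD.  Troughs follow the same cut.
    """
    after = np.flatnonzero(peaks.peak_times > boundary_h)
    if after.size == 0:
        logger.info("no peak after %.1f h: DD peak set empty", boundary_h)
        cut_t = np.inf
        n_ld = peaks.n_peaks
    else:
        n_ld = int(after[0]) + 1
        cut_t = peaks.peak_times[after[0]]
    tr_ld = peaks.trough_times <= cut_t
    ld = PeakSet(
        peaks.peak_times[:n_ld],
        peaks.peak_heights[:n_ld],
        peaks.trough_times[tr_ld],
        peaks.trough_heights[tr_ld],
    )
    dd = PeakSet(
        peaks.peak_times[n_ld:],
        peaks.peak_heights[n_ld:],
        peaks.trough_times[~tr_ld],
        peaks.trough_heights[~tr_ld],
    )
    return ld, dd


def phase_difference(phase_a_h: float, phase_b_h: float, circle_h: float = 24.0) -> float:
    """Signed minimal circular difference b − a, in (−circle/2, circle/2].

    Positive values mean b is phase-delayed relative to a; an exactly
    antipodal pair reports +circle/2.
    """
    d = float(np.mod(phase_b_h - phase_a_h, circle_h))
    if d > circle_h / 2.0 + 1e-12:
        d -= circle_h
    return d


class RhythmEstimator(BaseEstimator):
    """Full per-subject rhythm analysis as a scikit-learn-style estimator.

    ``fit`` takes one :class:`ActivityTrace` (or an already mean-normalized
    :class:`Series`) and exposes the fitted rhythm parameters as trailing-
    underscore attributes: ``period_h_``, ``phase_h_``, ``phase_ct_h_``,
    ``amplitude_``, ``g_factor_``, ``n_peaks_``, plus the intermediate
    ``smoothed_`` curve and ``peaks_``.
    """

    def __init__(
        self,
        weighted: bool = True,
        target_period_h: float = 24.0,
        percentile_half_h: float = PERCENTILE_HALF_WINDOW_H,
        loess_half_h: float = LOESS_HALF_WINDOW_H,
        amplitude_selector: str = "second_day",
        gap_weight_rule: str = "mean",
        edge_exclusion_h: float | None = None,
        min_prominence_rel: float = 1e-6,
    ):
        self.weighted = weighted
        self.target_period_h = target_period_h
        self.percentile_half_h = percentile_half_h
        self.loess_half_h = loess_half_h
        self.amplitude_selector = amplitude_selector
        self.gap_weight_rule = gap_weight_rule
        self.edge_exclusion_h = edge_exclusion_h
        self.min_prominence_rel = min_prominence_rel

    def fit(self, X: ActivityTrace | Series, y=None):
        if isinstance(X, ActivityTrace):
            normalized = normalize_by_mean(X)
        elif isinstance(X, Series):
            normalized = X
        else:
            raise TypeError("fit expects an ActivityTrace or a normalized Series")
        self.normalized_ = normalized
        self.smoothed_ = smooth_actogram(
            normalized,
            percentile_half_h=self.percentile_half_h,
            loess_half_h=self.loess_half_h,
        )
        vrange = float(np.ptp(self.smoothed_.values))
        all_peaks = find_extrema(
            self.smoothed_, min_prominence=self.min_prominence_rel * vrange
        )
        # Extrema within one LOESS half-window of either end come from
        # truncated (extrapolative) windows and sit up to ~1 h off; exclude
        # them when enough interior peaks remain to estimate a period.
        edge = self.loess_half_h if self.edge_exclusion_h is None else self.edge_exclusion_h
        trimmed = trim_peakset(
            all_peaks,
            float(self.smoothed_.times[0]) + edge,
            float(self.smoothed_.times[-1]) - edge,
        )
        if trimmed.n_peaks >= 2:
            self.peaks_ = trimmed
        else:
            logger.info("fewer than 2 interior peaks; keeping edge-region extrema")
            self.peaks_ = all_peaks
        self.n_peaks_ = self.peaks_.n_peaks
        w = peak_weights(self.peaks_) if self.weighted else None
        self.period_h_ = estimate_period(
            self.peaks_,
            weighted=self.weighted,
            weights=w,
            gap_weight_rule=self.gap_weight_rule,
        )
        self.phase_h_ = estimate_phase(
            self.peaks_, self.period_h_, weighted=self.weighted, weights=w
        )
        self.phase_ct_h_ = phase_to_ct(self.phase_h_, self.period_h_)
        try:
            self.amplitude_ = estimate_amplitude(
                self.smoothed_, self.peaks_, selector=self.amplitude_selector
            )
        except ValueError:
            self.amplitude_ = float("nan")
        self.g_factor_ = g_factor(normalized, target_period_h=self.target_period_h)
        return self

    def estimate_(self) -> RhythmEstimate:
        return RhythmEstimate(
            period_h=self.period_h_,
            phase_h=self.phase_h_,
            phase_ct_h=self.phase_ct_h_,
            amplitude=self.amplitude_,
            g_factor=self.g_factor_,
            n_peaks=self.n_peaks_,
        )


def analyze_activity_trace(trace: ActivityTrace, **params) -> RhythmEstimate:
    """Convenience one-shot rhythm analysis of one activity trace."""
    return RhythmEstimator(**params).fit(trace).estimate_()


__all__.append("analyze_activity_trace")
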