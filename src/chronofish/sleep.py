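"""Sleep scoring from larval velocity traces.

Movement is scored with a velocity hysteresis: a larva that is moving stops
when its speed drops below the stop threshold (0.59 cm/s) and a still larva
starts moving when its speed exceeds the start threshold (0.60 cm/s);
velocities inside the band preserve the current state.  Sleep in zebrafish
larvae is an inactive (still) bout lasting more than one minute — strictly:
a 60-s still run is not sleep, a 61-s run is.  Sleep is summarized as
minutes asleep per clock hour and as day/night totals over the lighting
schedule's light and dark epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .containers import VelocityTrace
from .schedule import LightCondition, LightSchedule

__all__ = [
    "V_START_CM_S",
    "V_STOP_CM_S",
    "MovementState",
    "SleepBout",
    "SleepSummary",
    "detect_movement_state",
    "extract_sleep_bouts",
    "summarize_sleep",
    "SleepScorer",
]

#: Start (still→moving) and stop (moving→still) velocity thresholds, cm/s.
V_START_CM_S = 0.60
V_STOP_CM_S = 0.59


@dataclass
class MovementState:
    """Per-sample MOVING/STILL classification (``moving`` is a boolean array)."""

    sample_s: float
    moving: np.ndarray
    v_start: float = V_START_CM_S
    v_stop: float = V_STOP_CM_S


@dataclass
class SleepBout:
    """One sleep bout; times in hours from recording start."""

    start_h: float
    end_h: float

    @property
    def duration_min(self) -> float:
        return (self.end_h - self.start_h) * 60.0


@dataclass
class SleepSummary:
    """Minutes asleep per clock hour plus day/night totals."""

    minutes_per_hour: np.ndarray
    day_total_min: float
    night_total_min: float

    @property
    def total_min(self) -> float:
        return float(self.minutes_per_hour.sum())


def detect_movement_state(
    trace: VelocityTrace,
    v_start: float = V_START_CM_S,
    v_stop: float = V_STOP_CM_S,
) -> MovementState:
    """Hysteresis state machine over a velocity trace.

    MOVING→STILL when v < ``v_stop``; STILL→MOVING when v > ``v_start``;
    velocities in [v_stop, v_start] preserve the current state.  The initial
    state is MOVING iff the first sample exceeds ``v_start``.
    """
    if v_stop > v_start:
        raise ValueError("v_stop must be <= v_start (hysteresis)")
    v = trace.values
    if np.any(v < 0):
        raise ValueError("negative velocities are invalid")
    n = v.size
    events = np.zeros(n, dtype=np.int8)
    events[v > v_start] = 1
    events[v < v_stop] = -1
    # Forward-fill the last threshold crossing; samples before any crossing
    # keep the initial state.
    idx = np.where(events != 0, np.arange(n), -1)
    np.maximum.accumulate(idx, out=idx)
    initial_moving = bool(n and v[0] > v_start)
    moving = np.where(idx >= 0, events[np.clip(idx, 0, None)] == 1, initial_moving)
    return MovementState(
        sample_s=trace.sample_s, moving=moving, v_start=v_start, v_stop=v_stop
    )


def extract_sleep_bouts(
    state: MovementState, min_duration_s: float = 60.0
) -> list[SleepBout]:
    """Maximal still runs strictly longer than ``min_duration_s`` as sleep bouts.

    A still run spanning samples i..j (inclusive) has duration
    ``(j − i + 1) · sample_s`` and covers ``[i·sample_s, (j+1)·sample_s)``.
    """
    still = ~np.asarray(state.moving, dtype=bool)
    n = still.size
    if n == 0:
        return []
    padded = np.concatenate(([False], still, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
    bouts = []
    for i, j in zip(starts, ends):
        dur_s = (j - i) * state.sample_s
        if dur_s > min_duration_s:
            bouts.append(
                SleepBout(start_h=i * state.sample_s / 3600.0, end_h=j * state.sample_s / 3600.0)
            )
    return bouts


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def summarize_sleep(
    bouts: list[SleepBout],
    schedule: LightSchedule,
    span_h: float | None = None,
) -> SleepSummary:
    """Apportion sleep bouts to clock hours and to day/night totals.

    Bout minutes are split across hour boundaries (and light/dark epoch
    boundaries) by exact overlap.  Day is the sum over LIGHT epochs and
    night over DARK epochs; DIM epochs contribute to hourly values but to
    neither total.
    """
    if span_h is None:
        span_h = schedule.total_h
    n_hours = int(np.ceil(span_h - 1e-9))
    minutes = np.zeros(max(n_hours, 1))
    day = night = 0.0
    for bout in bouts:
        if bout.start_h < -1e-9 or bout.end_h > span_h + 1e-9:
            raise ValueError(
                f"bout [{bout.start_h:.4f}, {bout.end_h:.4f}] h outside recording span"
            )
        for h in range(int(bout.start_h), min(int(np.ceil(bout.end_h)), n_hours)):
            minutes[h] += 60.0 * _overlap(bout.start_h, bout.end_h, h, h + 1.0)
        for start, end, epoch in schedule.bounds():
            ov = 60.0 * _overlap(bout.start_h, bout.end_h, start, end)
            if epoch.condition is LightCondition.LIGHT:
                day += ov
            elif epoch.condition is LightCondition.DARK:
                night += ov
    return SleepSummary(minutes_per_hour=minutes, day_total_min=day, night_total_min=night)


class SleepScorer(BaseEstimator):
    """End-to-end sleep scoring of one velocity trace, sklearn-style.

    After ``fit`` the scorer exposes ``state_``, ``bouts_``, ``summary_``,
    ``day_total_min_``, ``night_total_min_`` and ``total_sleep_min_``.
    """

    def __init__(
        self,
        v_start: float = V_START_CM_S,
        v_stop: float = V_STOP_CM_S,
        min_duration_s: float = 60.0,
    ):
        self.v_start = v_start
        self.v_stop = v_stop
        self.min_duration_s = min_duration_s

    def fit(self, X: VelocityTrace, y=None):
        if not isinstance(X, VelocityTrace):
            raise TypeError("fit expects a VelocityTrace")
        self.state_ = detect_movement_state(X, v_start=self.v_start, v_stop=self.v_stop)
        self.bouts_ = extract_sleep_bouts(self.state_, min_duration_s=self.min_duration_s)
        self.summary_ = summarize_sleep(self.bouts_, X.schedule, span_h=X.span_h)
        self.day_total_min_ = self.summary_.day_total_min
        self.night_total_min_ = self.summary_.night_total_min
        self.total_sleep_min_ = self.summary_.total_min
        return self
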