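"""In-memory containers for recordings and derived series.

``ActivityTrace`` holds one larva's distance moved per time bin (the tracker
export unit: cm per 10-min bin); ``VelocityTrace`` holds a fine-resolution
speed series used for sleep scoring; ``LumTrace`` holds one plate well's
bioluminescence counts.  ``Series`` is the shared carrier for normalized,
detrended, or smoothed curves: strictly increasing, uniformly spaced times in
hours with dimensionless values.

Bins are half-open ``[start, start + bin)``; stored times are bin left edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .schedule import LightSchedule

__all__ = ["Series", "ActivityTrace", "VelocityTrace", "LumTrace"]


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class Series:
    """Uniformly sampled time series (times in hours)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = _as_1d_float(self.times, "times")
        self.values = _as_1d_float(self.values, "values")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size < 2:
            raise ValueError("series needs at least 2 points")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
            raise ValueError("times must be uniformly spaced")

    @property
    def dt_h(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def span_h(self) -> float:
        return float(self.times[-1] - self.times[0])

    def with_values(self, values: np.ndarray) -> "Series":
        return Series(times=self.times.copy(), values=np.asarray(values, dtype=float))


@dataclass
class ActivityTrace:
    """Distance moved (cm) per time bin for one subject.

    ``truth`` carries simulator ground-truth parameters (period, phase,
    amplitude) when the trace is synthetic; ``None`` for real recordings.
    """

    subject_id: str
    group_label: str
    bin_min: float
    values: np.ndarray
    schedule: LightSchedule
    t0_ref: str = "ZT0"
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.values = _as_1d_float(self.values, "values")
        if self.values.size < 2:
            raise ValueError("activity trace needs at least 2 bins")
        if np.any(self.values < 0):
            raise ValueError("distance moved cannot be negative")
        if self.bin_min <= 0:
            raise ValueError("bin_min must be positive")

    @property
    def times_h(self) -> np.ndarray:
        """Bin left edges, hours from t0_ref."""
        return np.arange(self.values.size) * (self.bin_min / 60.0)

    def to_series(self) -> Series:
        return Series(times=self.times_h, values=self.values.copy())


@dataclass
class VelocityTrace:
    """Speed (cm/s) at uniform sub-second-to-second sampling for one subject."""

    subject_id: str
    sample_s: float
    values: np.ndarray
    schedule: LightSchedule
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.values = _as_1d_float(self.values, "values")
        if self.sample_s <= 0:
            raise ValueError("sample_s must be positive")

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.values.size) * (self.sample_s / 3600.0)

    @property
    def span_h(self) -> float:
        return self.values.size * self.sample_s / 3600.0


@dataclass
class LumTrace:
    """Bioluminescence counts over time for one plate well."""

    well_id: str
    sample_min: float
    values: np.ndarray
    schedule: LightSchedule
    dd_onset_h: float
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.values = _as_1d_float(self.values, "values")
        if self.values.size < 2:
            raise ValueError("luminescence trace needs at least 2 samples")
        if self.sample_min <= 0:
            raise ValueError("sample_min must be positive")

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.values.size) * (self.sample_min / 60.0)

    def to_series(self) -> Series:
        return Series(times=self.times_h, values=self.values.copy())
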