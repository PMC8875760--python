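"""Lighting schedules for behavioural and bioluminescence recordings.

A :class:`LightSchedule` is an ordered, contiguous partition of the recording
span into epochs of constant illumination (bright light, darkness, or dim
light).  Schedules drive the simulators (masking bursts, day/night transition
probabilities, the LD→DD switch) and the analysis (day/night sleep totals,
the LD/DD peak split).

Time is measured in decimal hours from the start of the recording; hour 0 is
the reference lights-on (ZT0 under an entraining cycle, projected CT0 under
constant conditions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "LightCondition",
    "Epoch",
    "LightSchedule",
    "make_light_schedule",
    "PROTOCOLS",
]


class LightCondition(str, Enum):
    LIGHT = "LIGHT"
    DARK = "DARK"
    DIM = "DIM"


#: Illuminance conventions used by the study protocols (lux).
DEFAULT_LUX = {
    LightCondition.LIGHT: 770.0,
    LightCondition.DARK: 0.0,
    LightCondition.DIM: 7.5,
}


@dataclass(frozen=True)
class Epoch:
    """One span of constant lighting: ``[start_h, end-of-epoch)``."""

    start_h: float
    condition: LightCondition
    illuminance_lux: float

    def __post_init__(self) -> None:
        if self.illuminance_lux < 0:
            raise ValueError("illuminance must be >= 0")


@dataclass(frozen=True)
class LightSchedule:
    """Contiguous lighting epochs covering ``[0, total_h)``."""

    epochs: tuple[Epoch, ...]
    total_h: float

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule needs at least one epoch")
        if self.total_h <= 0:
            raise ValueError("total_h must be positive")
        starts = [e.start_h for e in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch starts must be strictly increasing")
        if starts[-1] >= self.total_h:
            raise ValueError("last epoch starts at or beyond total_h")

    # -- queries ---------------------------------------------------------

    def bounds(self) -> list[tuple[float, float, Epoch]]:
        """(start, end, epoch) triples; the last epoch ends at ``total_h``."""
        starts = [e.start_h for e in self.epochs]
        ends = starts[1:] + [self.total_h]
        return list(zip(starts, ends, self.epochs))

    def condition_at(self, t_h: float) -> LightCondition:
        if not 0 <= t_h < self.total_h:
            raise ValueError(f"time {t_h} h outside schedule [0, {self.total_h})")
        for start, end, epoch in self.bounds():
            if start <= t_h < end:
                return epoch.condition
        raise AssertionError("unreachable: schedule covers [0, total_h)")

    def condition_mask(self, times_h: np.ndarray, condition: LightCondition) -> np.ndarray:
        """Boolean mask of ``times_h`` falling in epochs of ``condition``."""
        times_h = np.asarray(times_h, dtype=float)
        mask = np.zeros(times_h.shape, dtype=bool)
        for start, end, epoch in self.bounds():
            if epoch.condition is condition:
                mask |= (times_h >= start) & (times_h < end)
        return mask

    def transitions(
        self, from_condition: LightCondition, to_condition: LightCondition
    ) -> list[float]:
        """Interior epoch boundaries where ``from_condition`` → ``to_condition``."""
        out = []
        for prev, nxt in zip(self.epochs, self.epochs[1:]):
            if prev.condition is from_condition and nxt.condition is to_condition:
                out.append(nxt.start_h)
        return out

    def constant_tail_start_h(self) -> float:
        """Onset of a terminal free-running (constant-condition) span.

        Returns the start of the final epoch when that epoch outlasts a half
        cycle (12 h), i.e. the schedule has stopped cycling; otherwise the
        schedule is cyclic throughout and ``total_h`` is returned.
        """
        last = self.epochs[-1]
        if self.total_h - last.start_h > 12.0 + 1e-9:
            return last.start_h
        return self.total_h

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "total_h": self.total_h,
            "epochs": [
                [e.start_h, e.condition.value, e.illuminance_lux] for e in self.epochs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightSchedule":
        epochs = tuple(
            Epoch(float(s), LightCondition(c), float(lux)) for s, c, lux in d["epochs"]
        )
        return cls(epochs=epochs, total_h=float(d["total_h"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "LightSchedule":
        return cls.from_dict(json.loads(s))


def _cycles(
    day: LightCondition, night: LightCondition, n_days: int, lights_on_h: float, t0: float
) -> list[Epoch]:
    """12:12 day/night alternation for ``n_days``, starting at ``t0``."""
    if not 0 <= lights_on_h < 24:
        raise ValueError("lights_on_h must be in [0, 24)")
    epochs = []
    if lights_on_h > 0:
        epochs.append(Epoch(t0, night, DEFAULT_LUX[night]))
    for d in range(n_days):
        on = t0 + lights_on_h + 24.0 * d
        epochs.append(Epoch(on, day, DEFAULT_LUX[day]))
        off = on + 12.0
        if off < t0 + 24.0 * n_days:
            epochs.append(Epoch(off, night, DEFAULT_LUX[night]))
    return epochs


PROTOCOLS = (
    "LD",
    "LDIM",
    "DIMDIM",
    "DD",
    "LD_THEN_DD",
    "ENTRAIN_THEN_DIMDIM",
)


def make_light_schedule(
    protocol_name: str, n_days: int, lights_on_h: float = 0.0
) -> LightSchedule:
    """Build one of the study's lighting protocols.

    Parameters
    ----------
    protocol_name
        One of ``LD`` (12:12 light/dark), ``LDIM`` (12:12 light/dim),
        ``DIMDIM`` (constant dim, 7.5 lux), ``DD`` (constant dark),
        ``LD_THEN_DD`` (``n_days`` LD cycles followed by ``n_days`` of
        constant dark), or ``ENTRAIN_THEN_DIMDIM`` (3 LD + 2 LDim
        entrainment cycles followed by ``n_days`` of constant dim).
    n_days
        Number of days (cycles) of the protocol's main phase; must be >= 1.
    lights_on_h
        Clock hour of lights-on within each 24-h cycle, for cyclic protocols.
    """
    name = protocol_name.strip().upper().replace("-", "_")
    if name not in PROTOCOLS:
        raise ValueError(
            f"unknown protocol {protocol_name!r}; valid protocols: {', '.join(PROTOCOLS)}"
        )
    if n_days < 1:
        raise ValueError("n_days must be >= 1")

    L, D, M = LightCondition.LIGHT, LightCondition.DARK, LightCondition.DIM
    if name == "LD":
        return LightSchedule(
            tuple(_cycles(L, D, n_days, lights_on_h, 0.0)), 24.0 * n_days
        )
    if name == "LDIM":
        return LightSchedule(
            tuple(_cycles(L, M, n_days, lights_on_h, 0.0)), 24.0 * n_days
        )
    if name == "DIMDIM":
        return LightSchedule((Epoch(0.0, M, DEFAULT_LUX[M]),), 24.0 * n_days)
    if name == "DD":
        return LightSchedule((Epoch(0.0, D, DEFAULT_LUX[D]),), 24.0 * n_days)
    if name == "LD_THEN_DD":
        epochs = _cycles(L, D, n_days, lights_on_h, 0.0)
        epochs.append(Epoch(24.0 * n_days, D, DEFAULT_LUX[D]))
        return LightSchedule(tuple(epochs), 48.0 * n_days)
    # ENTRAIN_THEN_DIMDIM: 3 LD + 2 LDim cycles, then constant dim.
    epochs = _cycles(L, D, 3, lights_on_h, 0.0)
    epochs += _cycles(L, M, 2, lights_on_h, 72.0)
    epochs.append(Epoch(120.0, M, DEFAULT_LUX[M]))
    return LightSchedule(tuple(epochs), 120.0 + 24.0 * n_days)
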