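"""Synthetic recordings with known ground truth for every pipeline stage.

Three generators emulate the study's raw data:

* **Locomotor cohorts** — distance moved per 10-min bin with a clipped-cosine
  diel waveform, ``baseline · (1 + A · max(0, cos(2π(t − φ)/P)))``, which is
  nonnegative and daytime-peaked like real larval actograms.  Noise is
  multiplicative gamma (mean 1, shape 1/dispersion).  Between-subject
  heterogeneity draws each subject's period from Normal(P, period_sd) and
  phase from a wrapped Normal(φ, phase_jitter_sd).  An additive masking
  burst (``masking_gain · baseline`` in the first bins after every
  light→dark transition) emulates the acute startle response to lights-off.
* **Velocity traces** — a two-state (moving/still) Markov chain per sample
  with day/night-dependent transition probabilities; moving speed is drawn
  above the start threshold, still speed is 0.
* **Bioluminescence plates** — a cosine whose period switches from the LD to
  the DD value at the free-run onset (phase-continuous), with exponential
  amplitude damping after DD onset, a linear baseline trend, and additive
  Gaussian well noise.

All generators are pure functions of (config, schedule): a fixed config seed
reproduces output exactly.  Subjects and wells derive independent
sub-streams from (seed, index), so enlarging a cohort never reshuffles
earlier subjects.  Every trace records its ground-truth parameters so
downstream estimates can be checked by parameter recovery.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from .containers import ActivityTrace, LumTrace, VelocityTrace
from .schedule import LightCondition, LightSchedule

__all__ = [
    "LocomotorSimConfig",
    "SleepSimConfig",
    "LumSimConfig",
    "simulate_locomotor_cohort",
    "simulate_velocity_trace",
    "simulate_luminescence_plate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocomotorSimConfig:
    """Ground-truth parameters for a simulated locomotor cohort.

    Defaults give a diurnal larva: 24-h period peaking at hour 6, amplitude
    2 on a 20 cm/bin baseline, moderate multiplicative noise (CV ≈ 0.55),
    and mild between-subject spread in period and phase.
    """

    period_h: float = 24.0
    phase_h: float = 6.0
    amplitude: float = 2.0
    baseline_cm_per_bin: float = 20.0
    bin_min: float = 10.0
    n_days: int = 3
    phase_jitter_sd_h: float = 0.5
    period_sd_h: float = 0.25
    noise_dispersion: float = 0.3
    masking_gain: float = 1.5
    masking_bins: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError("period_h must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.baseline_cm_per_bin <= 0:
            raise ValueError("baseline must be positive")
        if self.bin_min <= 0:
            raise ValueError("bin_min must be positive")
        if min(self.phase_jitter_sd_h, self.period_sd_h, self.noise_dispersion) < 0:
            raise ValueError("SDs and dispersion must be >= 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


@dataclass(frozen=True)
class SleepSimConfig:
    """Two-state movement process parameters for sleep-scoring input.

    Per-step (``sample_s``) transition probabilities are day/night specific;
    defaults make larvae nocturnal sleepers: long still runs at night (mean
    start latency 1/p_start_night = 50 s) and brief pauses by day.
    """

    sample_s: float = 1.0
    p_stop_day: float = 0.005
    p_stop_night: float = 0.05
    p_start_day: float = 0.2
    p_start_night: float = 0.02
    moving_speed_mean: float = 1.2
    moving_speed_sd: float = 0.3
    n_hours: float = 24.0
    initial_moving: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_stop_day", "p_stop_night", "p_start_day", "p_start_night"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sample_s <= 0:
            raise ValueError("sample_s must be positive")
        if self.n_hours < 1:
            raise ValueError("n_hours must be >= 1")


@dataclass(frozen=True)
class LumSimConfig:
    """Damped drifting oscillation parameters for a bioluminescence plate."""

    period_ld_h: float = 24.0
    period_dd_h: float = 26.0
    phase_h: float = 6.0
    amplitude: float = 20.0
    damping_rate_per_h: float = 0.01
    trend_intercept: float = 100.0
    trend_slope_per_h: float = -0.05
    noise_sd: float = 2.0
    sample_min: float = 10.0
    n_wells: int = 8
    ld_cycles: int = 5
    dd_days: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_ld_h <= 0 or self.period_dd_h <= 0:
            raise ValueError("periods must be positive")
        if self.damping_rate_per_h < 0:
            raise ValueError("damping_rate must be >= 0")
        if self.sample_min <= 0:
            raise ValueError("sample_min must be positive")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")


def _clipped_cosine(t_h: np.ndarray, period_h: float, phase_h: float) -> np.ndarray:
    return np.clip(np.cos(2.0 * np.pi * (t_h - phase_h) / period_h), 0.0, None)


def simulate_locomotor_cohort(
    config: LocomotorSimConfig,
    schedule: LightSchedule,
    n_subjects: int,
    group_label: str = "sim",
) -> list[ActivityTrace]:
    """Simulate ``n_subjects`` activity traces over ``config.n_days`` days.

    Each trace's ``truth`` dict records the subject's drawn period, phase
    (on its own period circle), amplitude and baseline.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    duration_h = 24.0 * config.n_days
    if schedule.total_h < duration_h - 1e-9:
        raise ValueError(
            f"schedule ({schedule.total_h} h) shorter than requested {duration_h} h"
        )
    bin_h = config.bin_min / 60.0
    n_bins = int(round(duration_h / bin_h))
    t = np.arange(n_bins) * bin_h

    masking_add = np.zeros(n_bins)
    for tt in schedule.transitions(LightCondition.LIGHT, LightCondition.DARK):
        if tt >= duration_h:
            continue
        i0 = int(np.floor(tt / bin_h + 1e-9))
        masking_add[i0 : i0 + config.masking_bins] += (
            config.masking_gain * config.baseline_cm_per_bin
        )

    traces = []
    for i in range(n_subjects):
        rng = np.random.default_rng([config.seed, i])
        p_i = max(config.period_h + config.period_sd_h * rng.standard_normal(), 1e-3)
        phi_i = config.phase_h + config.phase_jitter_sd_h * rng.standard_normal()
        base = config.baseline_cm_per_bin * (
            1.0 + config.amplitude * _clipped_cosine(t, p_i, phi_i)
        )
        if config.noise_dispersion > 0:
            shape = 1.0 / config.noise_dispersion
            base = base * rng.gamma(shape, scale=1.0 / shape, size=n_bins)
        values = base + masking_add
        traces.append(
            ActivityTrace(
                subject_id=f"{group_label}_{i:03d}",
                group_label=group_label,
                bin_min=config.bin_min,
                values=values,
                schedule=schedule,
                truth={
                    "period_h": float(p_i),
                    "phase_h": float(np.mod(phi_i, p_i)),
                    "amplitude": float(config.amplitude),
                    "baseline_cm_per_bin": float(config.baseline_cm_per_bin),
                },
            )
        )
    return traces


def simulate_velocity_trace(config: SleepSimConfig, schedule: LightSchedule) -> VelocityTrace:
    """Simulate one larva's velocity trace from the two-state movement process.

    DARK and DIM epochs use the night transition probabilities (dim light is
    the rest phase of a light/dim cycle); LIGHT epochs use the day ones.
    """
    n = int(round(config.n_hours * 3600.0 / config.sample_s))
    t_h = np.arange(n) * (config.sample_s / 3600.0)
    is_day = schedule.condition_mask(
        np.clip(t_h, 0, schedule.total_h - 1e-9), LightCondition.LIGHT
    )
    rng = np.random.default_rng([config.seed, 0])
    u = rng.random(n)
    speeds = np.maximum(
        config.moving_speed_mean + config.moving_speed_sd * rng.standard_normal(n),
        0.61,
    )
    moving = np.empty(n, dtype=bool)
    state = config.initial_moving
    for j in range(n):
        p_stop = config.p_stop_day if is_day[j] else config.p_stop_night
        p_start = config.p_start_day if is_day[j] else config.p_start_night
        if state:
            if u[j] < p_stop:
                state = False
        else:
            if u[j] < p_start:
                state = True
        moving[j] = state
    values = np.where(moving, speeds, 0.0)
    return VelocityTrace(
        subject_id="sim_000",
        sample_s=config.sample_s,
        values=values,
        schedule=schedule,
        truth=asdict(config),
    )


def simulate_luminescence_plate(config: LumSimConfig, schedule: LightSchedule) -> list[LumTrace]:
    """Simulate a plate of bioluminescence wells over LD→DD.

    The oscillation is phase-continuous at the DD onset (taken from the
    schedule's constant tail): frequency switches from 1/period_ld to
    1/period_dd and the amplitude decays as exp(−damping·(t − onset)).
    """
    dd_onset = schedule.constant_tail_start_h()
    sample_h = config.sample_min / 60.0
    n_exact = schedule.total_h / sample_h
    n = int(np.floor(n_exact + 1e-9))
    if abs(n_exact - n) > 1e-9:
        logger.warning(
            "sample_min %.3g does not divide the %.3g h schedule evenly; "
            "dropping the final partial sample",
            config.sample_min,
            schedule.total_h,
        )
    t = np.arange(n) * sample_h

    before = t < dd_onset
    theta = np.empty(n)
    theta[before] = 2.0 * np.pi * (t[before] - config.phase_h) / config.period_ld_h
    theta0 = 2.0 * np.pi * (dd_onset - config.phase_h) / config.period_ld_h
    theta[~before] = theta0 + 2.0 * np.pi * (t[~before] - dd_onset) / config.period_dd_h
    decay = np.exp(-config.damping_rate_per_h * np.clip(t - dd_onset, 0.0, None))
    signal = (
        config.trend_intercept
        + config.trend_slope_per_h * t
        + config.amplitude * decay * np.cos(theta)
    )

    wells = []
    for w in range(config.n_wells):
        rng = np.random.default_rng([config.seed, w])
        noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
        wells.append(
            LumTrace(
                well_id=f"well_{w:02d}",
                sample_min=config.sample_min,
                values=signal + noise,
                schedule=schedule,
                dd_onset_h=dd_onset,
                truth={
                    "period_ld_h": config.period_ld_h,
                    "period_dd_h": config.period_dd_h,
                    "phase_h": config.phase_h,
                    "amplitude": config.amplitude,
                    "damping_rate_per_h": config.damping_rate_per_h,
                    "dd_onset_h": dd_onset,
                },
            )
        )
    return wells
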