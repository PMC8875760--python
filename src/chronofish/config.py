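"""Pipeline configuration: every tunable with its study default.

Defaults match the analysis constants used throughout: actogram smoothing
half-windows 3.33/8.33 h, moving-average full windows 29/9 h and LOESS full
windows 44/22 h for bioluminescence, velocity thresholds 0.60/0.59 cm/s,
>60 s sleep rule, 24-h G-factor target, 108-h LD/DD split, 10,000
permutations.  Configs round-trip through YAML; every pipeline run writes
its resolved config beside the outputs for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # actogram smoothing (half-window widths, hours)
    percentile_half_h: float = 10.0 / 3.0
    loess_half_h: float = 25.0 / 3.0
    # bioluminescence detrend/smooth (full window widths, hours)
    ma_detrend_window_h: float = 29.0
    ma_smooth_window_h: float = 9.0
    loess_detrend_window_h: float = 44.0
    loess_smooth_window_h: float = 22.0
    lum_method: str = "loess"  # "loess" or "moving_average"
    # rhythm estimation
    g_target_period_h: float = 24.0
    ld_dd_boundary_h: float = 108.0
    gap_weight_rule: str = "mean"
    weighted_activity: bool = True
    weighted_lum: bool = False
    # sleep scoring
    v_start_cm_s: float = 0.60
    v_stop_cm_s: float = 0.59
    sleep_min_duration_s: float = 60.0
    # statistics
    n_perm: int = 10_000
    fdr_level: float = 0.05
    # randomness
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
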