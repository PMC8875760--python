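"""End-to-end analysis stages chaining preprocessing, rhythm, sleep, stats.

These functions are the library behind the command-line interface: each takes
in-memory traces plus a :class:`~chronofish.config.PipelineConfig` and
returns tidy pandas tables / plain dicts ready to be written out.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import ActivityTrace, LumTrace, VelocityTrace
from .preprocess import loess, moving_average, standardize_well
from .rhythm import (
    RhythmEstimator,
    estimate_period,
    estimate_phase,
    find_extrema,
    phase_to_ct,
    split_ld_dd,
)
from .sleep import SleepScorer
from .stats import (
    CircularSample,
    bh_adjust,
    circular_mean,
    phases_to_angles,
    watson_williams,
    wilcoxon_rank_sum,
)
from . import rhythm as _rhythm

__all__ = [
    "analyze_activity_cohort",
    "analyze_sleep_cohort",
    "analyze_lum_plate",
    "compare_groups",
    "successive_amplitudes",
]


def analyze_activity_cohort(
    traces: list[ActivityTrace], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-subject rhythm results table (one row per larva)."""
    config = config or PipelineConfig()
    est = RhythmEstimator(
        weighted=config.weighted_activity,
        target_period_h=config.g_target_period_h,
        percentile_half_h=config.percentile_half_h,
        loess_half_h=config.loess_half_h,
        gap_weight_rule=config.gap_weight_rule,
    )
    rows = []
    for tr in traces:
        est.fit(tr)
        rows.append(
            {
                "subject_id": tr.subject_id,
                "group": tr.group_label,
                "period_h": est.period_h_,
                "phase_ct_h": est.phase_ct_h_,
                "amplitude": est.amplitude_,
                "g_factor": est.g_factor_,
                "n_peaks": est.n_peaks_,
            }
        )
    return pd.DataFrame(rows)


def analyze_sleep_cohort(
    traces: list[VelocityTrace], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly sleep minutes and day/night totals, one row per subject(-hour)."""
    config = config or PipelineConfig()
    scorer = SleepScorer(
        v_start=config.v_start_cm_s,
        v_stop=config.v_stop_cm_s,
        min_duration_s=config.sleep_min_duration_s,
    )
    hourly_rows, total_rows = [], []
    for tr in traces:
        scorer.fit(tr)
        for h, m in enumerate(scorer.summary_.minutes_per_hour):
            hourly_rows.append(
                {"subject_id": tr.subject_id, "hour": h, "minutes_asleep": m}
            )
        total_rows.append(
            {
                "subject_id": tr.subject_id,
                "day_total_min": scorer.day_total_min_,
                "night_total_min": scorer.night_total_min_,
                "total_min": scorer.total_sleep_min_,
                "n_bouts": len(scorer.bouts_),
            }
        )
    return pd.DataFrame(hourly_rows), pd.DataFrame(total_rows)


def successive_amplitudes(peaks, max_time_h: float = np.inf) -> np.ndarray:
    """Half peak-minus-preceding-trough heights for peaks up to ``max_time_h``."""
    amps = []
    for pt, ph in zip(peaks.peak_times, peaks.peak_heights):
        if pt > max_time_h:
            continue
        before = np.flatnonzero(peaks.trough_times < pt)
        if before.size == 0:
            continue
        amps.append((ph - peaks.trough_heights[before[-1]]) / 2.0)
    return np.asarray(amps)


def analyze_lum_plate(
    wells: list[LumTrace], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-well LD and DD rhythm parameters from detrended smoothed wells.

    Each well is standardized, detrended and smoothed (LOESS or moving
    average per config), peaks are split at the LD/DD boundary (the first
    peak after the 108-h last-light mark closes the LD set), and period,
    phase (rescaled to the 24-h clock) and successive peak amplitudes are
    estimated per segment.  Peaks within one smoothing half-window of the
    recording end are excluded: local regression is extrapolative there.
    """
    config = config or PipelineConfig()
    rows = []
    for well in wells:
        s = standardize_well(well)
        if config.lum_method == "loess":
            detr = loess(s, half_window_h=config.loess_detrend_window_h / 2.0, mode="detrend")
            smooth_half = config.loess_smooth_window_h / 2.0
            sm = loess(detr, half_window_h=smooth_half, mode="smooth")
        elif config.lum_method == "moving_average":
            detr = moving_average(s, config.ma_detrend_window_h, mode="detrend")
            smooth_half = config.ma_smooth_window_h / 2.0
            sm = moving_average(detr, config.ma_smooth_window_h, mode="smooth")
        else:
            raise ValueError("lum_method must be 'loess' or 'moving_average'")
        peaks = find_extrema(sm)
        ld, dd = split_ld_dd(peaks, boundary_h=config.ld_dd_boundary_h)
        edge_cut = float(s.times[-1]) - smooth_half
        for segment, pk in (("LD", ld), ("DD", dd)):
            keep = pk.peak_times <= edge_cut
            pk = type(pk)(
                pk.peak_times[keep],
                pk.peak_heights[keep],
                pk.trough_times,
                pk.trough_heights,
            )
            row = {
                "well_id": well.well_id,
                "segment": segment,
                "n_peaks": pk.n_peaks,
                "period_h": np.nan,
                "phase_circ_h": np.nan,
                "amplitudes": "",
            }
            if pk.n_peaks >= 2:
                period = estimate_period(pk, weighted=config.weighted_lum)
                phase = estimate_phase(pk, period, weighted=config.weighted_lum)
                row["period_h"] = period
                row["phase_circ_h"] = phase_to_ct(phase, period)
                amps = successive_amplitudes(pk)
                row["amplitudes"] = ";".join(f"{a:.6g}" for a in amps)
            rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    results: pd.DataFrame,
    config: PipelineConfig | None = None,
    circle_h: float = 24.0,
) -> dict:
    """Group comparison of a per-subject rhythm results table.

    Reports per-group circular mean phase (with resultant length), pairwise
    circular phase differences with Watson–Williams tests, Wilcoxon
    rank-sum tests on period, amplitude and G-factor, and BH-adjusted
    p-values over the family of pairwise comparisons.
    """
    config = config or PipelineConfig()
    groups = list(dict.fromkeys(results["group"]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    by_group = {g: results[results["group"] == g] for g in groups}

    group_summaries = {}
    for g, sub in by_group.items():
        angles = phases_to_angles(sub["phase_ct_h"].to_numpy(), circle_h)
        mean_dir, rbar = circular_mean(angles)
        group_summaries[g] = {
            "n": int(len(sub)),
            "phase_mean_ct_h": float(np.mod(mean_dir * circle_h / (2 * np.pi), circle_h)),
            "phase_resultant_length": rbar,
            "period_median_h": float(sub["period_h"].median()),
            "amplitude_median": float(np.nanmedian(sub["amplitude"])),
            "g_factor_median": float(sub["g_factor"].median()),
        }

    comparisons = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            a, b = by_group[ga], by_group[gb]
            ww = watson_williams(
                [
                    CircularSample(phases_to_angles(a["phase_ct_h"].to_numpy(), circle_h), label=ga),
                    CircularSample(phases_to_angles(b["phase_ct_h"].to_numpy(), circle_h), label=gb),
                ]
            )
            delta = _rhythm.phase_difference(
                group_summaries[ga]["phase_mean_ct_h"],
                group_summaries[gb]["phase_mean_ct_h"],
                circle_h,
            )
            entry = {
                "group_a": ga,
                "group_b": gb,
                "phase_difference_h": delta,
                "watson_williams": _test_dict(ww),
            }
            for metric in ("period_h", "amplitude", "g_factor"):
                va = a[metric].to_numpy(dtype=float)
                vb = b[metric].to_numpy(dtype=float)
                va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
                entry[f"wilcoxon_{metric}"] = _test_dict(wilcoxon_rank_sum(va, vb))
            comparisons.append(entry)

    raw_ps = []
    for entry in comparisons:
        raw_ps.append(entry["watson_williams"]["p_value"])
        for metric in ("period_h", "amplitude", "g_factor"):
            raw_ps.append(entry[f"wilcoxon_{metric}"]["p_value"])
    adjusted = bh_adjust(raw_ps)
    it = iter(adjusted)
    for entry in comparisons:
        entry["watson_williams"]["p_adjusted"] = float(next(it))
        for metric in ("period_h", "amplitude", "g_factor"):
            entry[f"wilcoxon_{metric}"]["p_adjusted"] = float(next(it))

    return {"groups": group_summaries, "comparisons": comparisons, "circle_h": circle_h}


def _test_dict(res) -> dict:
    return {
        "method": res.method,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "n": list(res.n),
        "warnings": list(res.warnings),
    }
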