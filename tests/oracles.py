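"""Independent brute-force oracles used by the test suite.

Each function recomputes a pipeline quantity by the most direct method
available (per-window loops, O(N²) sums, full enumeration, per-sample
scans), deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def moving_mean_oracle(values: np.ndarray, k: int) -> np.ndarray:
    """Centered moving mean, window of k points each side, truncated at edges."""
    n = len(values)
    return np.array(
        [np.mean(values[max(0, i - k) : min(n, i + k + 1)]) for i in range(n)]
    )


def moving_percentile_oracle(values: np.ndarray, k: int, q: float) -> np.ndarray:
    n = len(values)
    return np.array(
        [np.percentile(values[max(0, i - k) : min(n, i + k + 1)], q) for i in range(n)]
    )


def loess_oracle(times: np.ndarray, values: np.ndarray, k: int) -> np.ndarray:
    """Per-point tricube weighted degree-1 fit, truncated windows.

    Distances are scaled by (k + 1) sample spacings, matching the package's
    pinned convention, but the fit itself is an independent lstsq solve.
    """
    n = len(values)
    dt = times[1] - times[0]
    scale = (k + 1) * dt
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - k), min(n, i + k + 1)
        x = times[lo:hi] - times[i]
        y = values[lo:hi]
        w = np.clip(1 - (np.abs(x) / scale) ** 3, 0, None) ** 3
        sw = np.sqrt(w)
        A = np.stack([np.ones_like(x), x], axis=1)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        out[i] = coef[0]
    return out


def dft_power_oracle(values: np.ndarray, dt_h: float):
    """O(N²) direct-sum periodogram over positive frequencies, DC excluded."""
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    n = x.size
    j = np.arange(n)
    freqs, power = [], []
    for k in range(1, n // 2 + 1):
        c = np.sum(x * np.cos(2 * np.pi * k * j / n))
        s = np.sum(x * np.sin(2 * np.pi * k * j / n))
        freqs.append(k / (n * dt_h))
        power.append(c * c + s * s)
    return np.array(freqs), np.array(power)


def sleep_oracle(
    velocities: np.ndarray,
    sample_s: float,
    schedule,
    v_start: float = 0.60,
    v_stop: float = 0.59,
    min_duration_s: float = 60.0,
):
    """Per-sample scan: hysteresis states, still runs, hourly/day/night minutes.

    Returns (minutes_per_hour, day_total_min, night_total_min).
    """
    n = len(velocities)
    moving = velocities[0] > v_start if n else True
    states = []
    for v in velocities:
        if moving and v < v_stop:
            moving = False
        elif not moving and v > v_start:
            moving = True
        states.append(moving)

    # still runs -> sleep intervals in seconds
    intervals = []
    i = 0
    while i < n:
        if not states[i]:
            j = i
            while j < n and not states[j]:
                j += 1
            if (j - i) * sample_s > min_duration_s:
                intervals.append((i * sample_s, j * sample_s))
            i = j
        else:
            i += 1

    span_h = n * sample_s / 3600.0
    n_hours = int(np.ceil(span_h - 1e-9))
    minutes = np.zeros(max(n_hours, 1))
    day = night = 0.0
    bounds = schedule.bounds()
    for s0, s1 in intervals:
        for h in range(n_hours):
            ov = max(0.0, min(s1, (h + 1) * 3600.0) - max(s0, h * 3600.0))
            minutes[h] += ov / 60.0
        for e0, e1, epoch in bounds:
            ov = max(0.0, min(s1, e1 * 3600.0) - max(s0, e0 * 3600.0))
            if epoch.condition.value == "LIGHT":
                day += ov / 60.0
            elif epoch.condition.value == "DARK":
                night += ov / 60.0
    return minutes, day, night


def mann_whitney_u(x, y) -> int:
    return int(sum(xi > yj for xi in x for yj in y))


def wilcoxon_exact_oracle(a, b) -> float:
    """Two-sided exact rank-sum p by full enumeration of group labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    n1, n2 = len(a), len(b)
    t_obs = max(mann_whitney_u(a, b), n1 * n2 - mann_whitney_u(a, b))
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        chosen = set(idx)
        x = [pooled[i] for i in idx]
        y = [pooled[i] for i in range(n1 + n2) if i not in chosen]
        u = mann_whitney_u(x, y)
        count += max(u, n1 * n2 - u) >= t_obs
        total += 1
    return count / total


def bh_oracle(p_values) -> np.ndarray:
    """Step-up BH adjustment computed by hand (sort, scale, cummin, cap)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def circular_distance_h(a: float, b: float, circle_h: float = 24.0) -> float:
    """Unsigned minimal distance between two clock phases, hours."""
    d = abs(a - b) % circle_h
    return min(d, circle_h - d)
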