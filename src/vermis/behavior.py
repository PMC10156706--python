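"""Saccade detection, kinematics extraction and behavioral comparisons.

Saccades are detected on the 1-kHz eye-position trace by differentiating
(central difference, light boxcar smoothing) and thresholding the absolute
velocity at 30 deg/s; primary saccades are those of 13-17 deg amplitude.
Endpoint errors are classified as inward (overshoot) or outward
(undershoot) relative to the target.  The early/late fatigue comparison
applies paired two-sided Wilcoxon signed-rank tests to the first and last
n = 30 trials of a session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig, DEFAULT_CONFIG
from .io import SessionBundle
from .stats import wilcoxon_signed_rank

__all__ = [
    "SaccadeTrial",
    "detect_saccades",
    "velocity_from_position",
    "compute_kinematics",
    "classify_endpoint_error",
    "extract_trials",
    "bin_by_peak_velocity",
    "compare_early_late",
]


@dataclass
class SaccadeTrial:
    """Kinematics and error labels of one detected saccade."""

    trial_index: int
    direction: str
    type: str
    onset_ms: float
    offset_ms: float
    peak_velocity: float
    duration_ms: float
    amplitude: float
    endpoint_error: float
    error_type: str
    error_direction: str


def velocity_from_position(
    position: np.ndarray, config: RunConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Velocity (deg/s) by central difference plus a short boxcar."""
    rate = config.sample_rate_hz
    v = np.gradient(np.asarray(position, float)) * rate
    width = max(int(round(config.velocity_smoothing_ms * rate / 1000.0)), 1)
    if width > 1:
        kernel = np.ones(width) / width
        v = np.convolve(v, kernel, mode="same")
    return v


def detect_saccades(
    position: np.ndarray,
    config: RunConfig = DEFAULT_CONFIG,
    velocity: np.ndarray | None = None,
    amplitude_filter: bool = False,
) -> list[tuple[int, int]]:
    """Maximal intervals where |velocity| >= the 30 deg/s threshold.

    Intervals separated by sub-threshold gaps shorter than the configured
    minimum are merged; with ``amplitude_filter`` only primary saccades of
    13-17 deg amplitude are kept.  Returns (onset, offset) sample indices;
    an empty list if nothing crosses threshold.
    """
    if velocity is None:
        velocity = velocity_from_position(position, config)
    above = np.abs(velocity) >= config.velocity_threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above))
    gap = config.merge_gap_ms * config.sample_rate_hz / 1000.0
    merged = []
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    min_len = config.min_saccade_duration_ms * config.sample_rate_hz / 1000.0
    merged = [(s, e) for s, e in merged if e - s >= min_len]
    if amplitude_filter:
        keep = []
        for s, e in merged:
            amp = abs(position[min(e, len(position) - 1)] - position[s])
            if config.primary_amplitude_min <= amp <= config.primary_amplitude_max:
                keep.append((s, e))
        merged = keep
    return merged


def compute_kinematics(
    position: np.ndarray,
    interval: tuple[int, int],
    config: RunConfig = DEFAULT_CONFIG,
    velocity: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(peak velocity, duration ms, amplitude deg) on a detected interval."""
    if interval is None:
        raise ValueError("no detected saccade")
    if velocity is None:
        velocity = velocity_from_position(position, config)
    s, e = interval
    pv = float(np.abs(velocity[s:e]).max())
    duration = (e - s) * 1000.0 / config.sample_rate_hz
    amp = float(abs(position[min(e, len(position) - 1)] - position[s]))
    return pv, duration, amp


def classify_endpoint_error(
    endpoint: float,
    target: float,
    direction: str,
    floor: float = DEFAULT_CONFIG.error_floor_deg,
) -> tuple[str, str]:
    """Label the post-saccadic retinal error.

    Undershoot (eye short of the target along the movement direction) is an
    outward error; overshoot is inward.  The error direction is the sign of
    the target-minus-eye residual on the horizontal axis.
    """
    residual = target - endpoint
    if abs(residual) < floor:
        return "none", "none"
    d = 1.0 if direction == "right" else -1.0
    error_type = "outward" if residual * d > 0 else "inward"
    error_direction = "right" if residual > 0 else "left"
    return error_type, error_direction


def extract_trials(
    bundle: SessionBundle, config: RunConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Re-derive per-trial kinematics and error labels from the eye traces.

    The largest-amplitude detected saccade per trial is taken as the
    primary saccade; its endpoint is compared against the trial's target
    position.  Returns a trial table in the bundle layout.
    """
    rows = []
    for _, tr in bundle.trials.iterrows():
        ti = int(tr["trial_index"])
        if ti not in bundle.traces:
            continue
        pos = bundle.traces[ti]["position"]
        vel = velocity_from_position(pos, config)
        intervals = detect_saccades(pos, config, velocity=vel)
        if not intervals:
            continue
        s, e = max(intervals, key=lambda se: abs(pos[min(se[1], len(pos) - 1)] - pos[se[0]]))
        pv, dur, amp = compute_kinematics(pos, (s, e), config, velocity=vel)
        endpoint = float(pos[min(e, len(pos) - 1)])
        etype, edir = classify_endpoint_error(
            endpoint, float(tr["target_position"]), tr["direction"], config.error_floor_deg
        )
        rows.append(
            dict(
                trial_index=ti,
                type=tr["type"],
                direction=tr["direction"],
                onset_ms=s * 1000.0 / config.sample_rate_hz,
                offset_ms=e * 1000.0 / config.sample_rate_hz,
                pv=pv,
                duration_ms=dur,
                amplitude=amp,
                endpoint_error=endpoint - float(tr["target_position"]),
                error_type=etype,
                error_direction=edir,
            )
        )
    return pd.DataFrame(rows)


def bin_by_peak_velocity(
    trials: pd.DataFrame, config: RunConfig = DEFAULT_CONFIG
) -> dict[tuple[float, float], pd.DataFrame]:
    """Partition trials into half-open PV bins [k*50, (k+1)*50) deg/s.

    Bins holding fewer than the configured minimum trial count are dropped.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    size = config.pv_bin_size
    idx = np.floor(trials["pv"].to_numpy(float) / size).astype(int)
    out = {}
    for k in sorted(set(idx)):
        sub = trials[idx == k]
        if len(sub) >= config.min_trials_per_bin:
            out[(k * size, (k + 1) * size)] = sub
    return out


def compare_early_late(
    trials: pd.DataFrame,
    n: int | None = None,
    measures: tuple = ("pv", "duration_ms", "amplitude"),
    config: RunConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Wilcoxon signed-rank comparison of the first vs last ``n`` trials.

    Trials are paired by rank order within the early and late blocks.
    Returns a table of (measure, statistic, p, median change %).
    """
    n = config.early_late_n if n is None else n
    if len(trials) < 2 * n:
        raise ValueError(f"need at least {2 * n} trials, got {len(trials)}")
    trials = trials.sort_values("trial_index")
    rows = []
    for m in measures:
        early = np.sort(trials[m].to_numpy(float)[:n])
        late = np.sort(trials[m].to_numpy(float)[-n:])
        stat, p = wilcoxon_signed_rank(late, early)
        med_early, med_late = np.median(early), np.median(late)
        change = (med_late - med_early) / med_early * 100.0 if med_early else np.nan
        rows.append(dict(measure=m, statistic=stat, p=p, median_change_pct=change,
                         n=n))
    return pd.DataFrame(rows)
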