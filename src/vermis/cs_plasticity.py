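"""Complex-spike conditioned manifold plasticity.

Complex spikes (CS) fired in the post-saccadic error window report retinal
errors whose direction matches a Purkinje cell's CS-ON direction.  To pool
the whole population into simulated error conditions, trials are combined
per unit: CS trials of PCs whose CS-ON direction matches the simulated
error vector, and no-CS trials of the remaining (CS-OFF) PCs — a unit
reports the error either by firing a CS or by not firing one.  The trials
*following* the pooled trials are then used to re-fit per-unit rate models
(peak velocity as the kinematic parameter) and compare the resulting
manifolds: size/rotation-speed curves over a common PV grid and their
slope angles normalized by the no-CS control, with one-sided t tests on
the leave-one-unit-out jackknife angle distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig, DEFAULT_CONFIG
from .manifolds import (
    PopulationManifold,
    manifold_size,
    rotation_speed,
    slope_angle,
    smooth_trajectory,
)
from .rate_models import PopulationRateModel
from .stats import one_sided_t

log = logging.getLogger("vermis")

__all__ = [
    "CSCondition",
    "estimate_cs_on_direction",
    "cs_trial_mask",
    "pool_simulated_error_trials",
    "conditioned_manifold_comparison",
    "ConditionedComparison",
    "post_cs_velocity_change",
]


@dataclass(frozen=True)
class CSCondition:
    """A simulated error condition: error type and CS timing window."""

    error_type: str                       # "outward", "inward" or "none"
    window: tuple = (50.0, 140.0)         # ms from saccade offset, half-open
    error_direction: str | None = None    # optional direction control filter


def cs_trial_mask(
    cs_by_trial: dict, trial_indices: np.ndarray, window: tuple
) -> np.ndarray:
    """Boolean mask: trial has >= 1 CS inside the half-open window [a, b)."""
    a, b = window
    out = np.zeros(len(trial_indices), dtype=bool)
    for i, ti in enumerate(trial_indices):
        cs = cs_by_trial.get(int(ti))
        if cs is not None and cs.size and np.any((cs >= a) & (cs < b)):
            out[i] = True
    return out


def estimate_cs_on_direction(
    cs_by_trial: dict,
    trials: pd.DataFrame,
    config: RunConfig = DEFAULT_CONFIG,
) -> str | None:
    """CS-ON direction: the error direction evoking the larger CS rate.

    Compares mean CS counts in the early error window between leftward-
    and rightward-error trials; returns None when unresolved (tie or too
    few error trials per direction).
    """
    window = config.cs_window_early
    rates = {}
    for d in ("left", "right"):
        sub = trials[trials["error_direction"] == d]
        if len(sub) < config.cs_min_trials_per_direction:
            return None
        counts = []
        a, b = window
        for ti in sub["trial_index"]:
            cs = cs_by_trial.get(int(ti), np.empty(0))
            counts.append(np.sum((cs >= a) & (cs < b)))
        rates[d] = float(np.mean(counts))
    if rates["left"] == rates["right"]:
        return None
    return "left" if rates["left"] > rates["right"] else "right"


def _simulated_error_direction(error_type: str, movement_direction: str) -> str:
    """Error vector direction of a simulated error for a given movement.

    An undershoot leaves the target beyond the endpoint (outward error
    pointing along the movement); an overshoot points back (inward)."""
    other = {"left": "right", "right": "left"}
    return movement_direction if error_type == "outward" else other[movement_direction]


def pool_simulated_error_trials(
    cs_on: dict,
    cs_events: dict,
    trials: pd.DataFrame,
    condition: CSCondition,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict:
    """Per-unit trial pools for a simulated error condition.

    ``cs_on`` maps unit id -> CS-ON direction, ``cs_events`` maps unit id
    -> {trial -> CS-time array (ms from saccade offset)}.  ``trials`` are
    the (centrifugal) trials the condition draws from, ordered in time.
    For each unit the pool holds its CS trials when its CS-ON direction
    matches the simulated error vector and its no-CS trials otherwise
    (every unit's trials are partitioned by the window rule); returned are
    both the pooled trial indices and the indices of the next same-type
    trials used for post-condition analyses (the session's last trial
    contributes no post trial).
    """
    trials = trials.sort_values("trial_index")
    order = trials["trial_index"].to_numpy(int)
    nxt = {int(a): int(b) for a, b in zip(order[:-1], order[1:])}
    pools = {}
    for uid, direction in cs_on.items():
        if direction is None:
            log.info("pooling: unit %s has unresolved CS-ON; dropped", uid)
            continue
        mask = cs_trial_mask(cs_events[uid], order, condition.window)
        if condition.error_type == "none":
            take = ~mask
        else:
            sim_dir = _simulated_error_direction(
                condition.error_type, str(trials["direction"].iloc[0])
            )
            if condition.error_direction is not None and sim_dir != condition.error_direction:
                pools[uid] = (np.empty(0, int), np.empty(0, int))
                continue
            take = mask if direction == sim_dir else ~mask
        pool = order[take]
        post = np.array([nxt[t] for t in pool if t in nxt], dtype=int)
        if pool.size == 0:
            log.info("pooling: unit %s has an empty pool; dropped", uid)
            continue
        pools[uid] = (pool, post)
    return pools


@dataclass
class ConditionedComparison:
    """Per-condition manifold metrics and slope-angle tests."""

    metrics: pd.DataFrame          # condition, pv, size, speed
    angles: dict                   # condition -> full-sample angle
    jackknife_angles: dict         # condition -> per-leave-out angle array
    tests: pd.DataFrame            # pair, t, p (one-sided)
    control_sds: tuple
    dropped_units: dict = field(default_factory=dict)


def _condition_metrics(
    R0: np.ndarray,
    dRdPV: np.ndarray,
    pv_grid: np.ndarray,
    pv0: float,
    time_ms: np.ndarray,
    config: RunConfig,
) -> tuple[np.ndarray, np.ndarray]:
    # geometry is computed on the core analysis window (trajectories start
    # at -250 ms with phase ~ -180 deg) and a lightly smoothed trajectory
    window = (time_ms >= config.grid_start_ms) & (time_ms < config.grid_stop_ms)
    man = PopulationManifold(variance_threshold=config.variance_threshold).fit(
        R0, {"pv": dRdPV}
    )
    sizes, speeds = [], []
    for pv in pv_grid:
        P = man.evaluate_trajectory({"pv": pv - pv0})[:2, window]
        xy = smooth_trajectory(P, config.trajectory_smoothing_sd_ms / config.bin_ms).T
        sizes.append(manifold_size(xy))
        speeds.append(rotation_speed(xy, time_ms[window])[0])
    return np.array(sizes), np.array(speeds)


def conditioned_manifold_comparison(
    unit_rates: dict,
    trials: pd.DataFrame,
    pools_by_condition: dict,
    time_ms: np.ndarray,
    config: RunConfig = DEFAULT_CONFIG,
    control: str = "none",
) -> ConditionedComparison:
    """Compare manifolds re-fitted on the post trials of each pool.

    ``unit_rates`` maps unit id -> (n_trials, T) per-trial smoothed rates
    over the centrifugal trials of ``trials`` (same row order);
    ``pools_by_condition`` maps condition name -> per-unit pools from
    :func:`pool_simulated_error_trials`.
    """
    trials = trials.sort_values("trial_index").reset_index(drop=True)
    row_of = {int(t): i for i, t in enumerate(trials["trial_index"])}
    pv_all = trials["pv"].to_numpy(float)
    pv_grid = np.linspace(
        *np.percentile(pv_all, config.pv_grid_percentiles), config.pv_grid_points
    )

    fits = {}       # condition -> (R0 matrix, dRdPV matrix, unit ids, pv0)
    dropped = {}
    for cond, pools in pools_by_condition.items():
        rows_R0, rows_d, kept, z0s = [], [], [], []
        for uid, (_pool, post) in pools.items():
            post_rows = [row_of[t] for t in post if t in row_of]
            if len(post_rows) < config.min_pool_trials:
                dropped.setdefault(cond, []).append(uid)
                log.info(
                    "condition %s: unit %s pool too small (%d < %d); dropped",
                    cond, uid, len(post_rows), config.min_pool_trials,
                )
                continue
            model = PopulationRateModel(
                param_names=("pv",),
                baseline_window=config.baseline_window,
                time_ms=time_ms,
            ).fit([unit_rates[uid][post_rows]], [pv_all[post_rows][:, None]])
            rows_R0.append(model.R0_[0])
            rows_d.append(model.dRdz_["pv"][0])
            z0s.append(model.z0_[0, 0])
            kept.append(uid)
        if len(kept) < 3:
            raise ValueError(
                f"condition {cond!r}: only {len(kept)} units with pools of "
                f">= {config.min_pool_trials} trials; cannot fit a manifold"
            )
        fits[cond] = (np.stack(rows_R0), np.stack(rows_d), kept, float(np.mean(z0s)))

    # full-sample metrics; control SDs normalize all conditions
    raw = {
        cond: _condition_metrics(R0, dD, pv_grid, pv0, time_ms, config)
        for cond, (R0, dD, _, pv0) in fits.items()
    }
    ctrl_sizes, ctrl_speeds = raw[control]
    control_sds = (
        float(np.std(ctrl_sizes, ddof=0)),
        float(np.std(ctrl_speeds, ddof=0)),
    )
    metrics = pd.concat(
        [
            pd.DataFrame(
                dict(condition=cond, pv=pv_grid, size=raw[cond][0], speed=raw[cond][1])
            )
            for cond in fits
        ],
        ignore_index=True,
    )
    angles = {
        cond: slope_angle(raw[cond][0], raw[cond][1], control_sds) for cond in fits
    }

    jack = {}
    for cond, (R0, dD, kept, pv0) in fits.items():
        vals = []
        for i in range(len(kept)):
            idx = [j for j in range(len(kept)) if j != i]
            s, sp = _condition_metrics(R0[idx], dD[idx], pv_grid, pv0, time_ms, config)
            vals.append(slope_angle(s, sp, control_sds))
        jack[cond] = np.array(vals)

    pairs = [(control, "outward"), ("inward", control), ("inward", "outward")]
    rows = []
    for a, b in pairs:
        if a in jack and b in jack:
            t, p = one_sided_t(jack[a], jack[b], alternative="greater")
            rows.append(dict(pair=f"{a}>{b}", t=t, p=p))
    return ConditionedComparison(
        metrics=metrics,
        angles=angles,
        jackknife_angles=jack,
        tests=pd.DataFrame(rows),
        control_sds=control_sds,
        dropped_units=dropped,
    )


def post_cs_velocity_change(
    velocities: dict,
    trials: pd.DataFrame,
    pools: dict,
) -> dict:
    """Velocity-profile change from pooled CS trials to their next trials.

    ``velocities`` maps trial index -> onset-aligned velocity trace (equal
    lengths).  Returns the time-resolved mean difference (post - CS) with
    pointwise paired two-sided t tests, plus summary PV and duration
    changes from the trial table.
    """
    from scipy import stats as sps

    cs_rows, post_rows = [], []
    for uid, (pool, post) in pools.items():
        paired = [(a, b) for a, b in zip(pool, post) if a in velocities and b in velocities]
        cs_rows += [a for a, _ in paired]
        post_rows += [b for _, b in paired]
    if len(cs_rows) < 2:
        raise ValueError("need at least 2 (CS, post) trial pairs")
    V_cs = np.stack([velocities[t] for t in cs_rows])
    V_post = np.stack([velocities[t] for t in post_rows])
    diff = V_post - V_cs
    tstat, pvals = sps.ttest_rel(V_post, V_cs, axis=0)
    tr = trials.set_index("trial_index")
    pv_change = (
        tr.loc[post_rows, "pv"].mean() / tr.loc[cs_rows, "pv"].mean() - 1.0
    ) * 100.0
    dur_change = (
        tr.loc[post_rows, "duration_ms"].mean() / tr.loc[cs_rows, "duration_ms"].mean()
        - 1.0
    ) * 100.0
    return dict(
        mean_difference=diff.mean(axis=0),
        sem_difference=diff.std(axis=0, ddof=1) / np.sqrt(diff.shape[0]),
        t=tstat,
        p=pvals,
        n_pairs=diff.shape[0],
        pv_change_pct=float(pv_change),
        duration_change_pct=float(dur_change),
    )
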