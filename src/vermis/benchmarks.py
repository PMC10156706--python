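"""Self-contained validation experiments on synthetic data.

Each function generates its inputs from a seed, runs one pipeline component
and measures how well known structure is recovered: the perturbation
prediction of manifold trajectories against a direct PCA re-fit, geometry
statistics against closed forms, rate-model and classifier parameter
recovery, feed-forward-network exactness and planted-structure recovery,
resampling/test calibration, and the end-to-end complex-spike conditioned
slope-angle ordering.  The problem sizes are chosen to run on a single CPU
in minutes; they are stated in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import orthogonal_procrustes

from .classify import (
    classify_mf_unit,
    classify_pc_pca_lda,
    gaussian_smooth,
    label_pc_by_threshold,
    perievent_rate,
)
from .config import DEFAULT_CONFIG, RunConfig
from .cs_plasticity import (
    CSCondition,
    conditioned_manifold_comparison,
    estimate_cs_on_direction,
    pool_simulated_error_trials,
)
from .lffn import (
    LinearFeedforwardModel,
    communication_subspace,
    manifold_limited_prediction,
)
from .manifolds import PopulationManifold, manifold_size, rotation_speed
from .rate_models import fit_unit_rate_model
from .stats import jackknife_mean_sem
from .synth import (
    SessionConfig,
    TRADEOFF_RATIO,
    _draw_mf_params,
    generate_kinematics_sequence,
    generate_session,
    mf_intensity,
    sample_spikes,
)

__all__ = [
    "eq2_oracle",
    "geometry_closed_forms",
    "rate_model_recovery",
    "classifier_accuracy",
    "cs_on_recovery",
    "lffn_checks",
    "stats_calibration",
    "cs_ordering_experiment",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def _smooth_patterns(rng, k, T):
    t = np.linspace(-250, 400, T)
    out = []
    for _ in range(k):
        c = rng.uniform(-200, 350, 4)
        w = rng.uniform(20, 80, 4)
        a = rng.normal(0, 1, 4)
        out.append(sum(ai * np.exp(-0.5 * ((t - ci) / wi) ** 2)
                       for ai, ci, wi in zip(a, c, w)))
    return np.array(out)


# ----------------------------------------------------------------------
# criterion experiments
# ----------------------------------------------------------------------

def eq2_oracle(seed: int, n_units: int = 50, T: int = 651) -> dict:
    """Perturbation-predicted trajectories vs direct PCA re-fit.

    A smooth synthetic population (N x T) is perturbed by dz times a random
    smooth derivative matrix; the first-order prediction is compared with
    the PCA of the perturbed rates after Procrustes alignment, at dz = 0.5
    and 0.25 trial SD.
    """
    rng = np.random.default_rng(seed)
    B = _smooth_patterns(rng, 6, T)
    load = rng.normal(0, 1, (n_units, 6)) * np.array([30, 18, 10, 6, 3, 2])
    R0 = load @ B
    D = rng.normal(0, 1, (n_units, 8)) @ _smooth_patterns(rng, 8, T) * 0.5
    sd = 0.1 * np.linalg.norm(R0) / np.linalg.norm(D)
    man = PopulationManifold().fit(R0, {"z": D})

    def rel_err(dz):
        pred = man.evaluate_trajectory({"z": dz})
        ref = PopulationManifold(n_components=man.K_).fit(R0 + dz * D)
        om, _ = orthogonal_procrustes(ref.W_, man.W_)
        return float(np.linalg.norm(pred - om.T @ ref.P_) / np.linalg.norm(man.P_))

    e_half, e_quarter = rel_err(0.5 * sd), rel_err(0.25 * sd)
    return dict(
        rel_error=e_half,
        rel_error_quarter=e_quarter,
        halving_ratio=e_half / e_quarter,
        n=n_units,
    )


def geometry_closed_forms() -> dict:
    """Manifold geometry statistics against analytic values."""
    th = np.radians(np.arange(0, 360, 1.0))
    circle = np.c_[np.cos(th), np.sin(th)]
    ellipse = np.c_[3 * np.cos(th), 2 * np.sin(th)]
    rng = np.random.default_rng(0)
    ang = np.sort(rng.uniform(0, 2 * np.pi, 40))
    rad = rng.uniform(0.5, 2.0, 40)
    poly = np.c_[rad * np.cos(ang), rad * np.sin(ang)]
    x, y = poly[:, 0], poly[:, 1]
    shoelace = abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    s = np.linspace(0, 1, 301)
    loop = np.c_[1 + np.cos(np.radians(-180 + 270 * s)),
                 np.sin(np.radians(-180 + 270 * s))]
    speed, _ = rotation_speed(loop, -250 + 300 * s)
    return dict(
        circle_rel_error=abs(manifold_size(circle) - np.pi) / np.pi,
        ellipse_rel_error=abs(manifold_size(ellipse) - 6 * np.pi) / (6 * np.pi),
        polygon_abs_diff=abs(manifold_size(poly) - shoelace),
        uniform_rotation_speed=float(speed),
        n=th.size,
    )


def rate_model_recovery(
    seed: int, n_units: int = 48, n_trials: int = 300,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict:
    """Recovery of a planted kinematic derivative from Poisson spiking.

    Rates are generated exactly as R0(t) + dPV * g(t) (a pedestal keeps the
    intensity positive over the PV range); the fitted derivative is
    compared with the smoothing-matched planted g over the 10% of time bins
    where |g| is largest, pooled across units.
    """
    rng = np.random.default_rng(seed)
    grid = np.arange(config.mf_grid_start_ms, config.mf_grid_stop_ms,
                     config.bin_ms) + config.bin_ms / 2
    pv = rng.uniform(300, 700, n_trials)
    pv0 = 500.0

    def tradeoff(p):
        return 15.0 / (TRADEOFF_RATIO * p) * 1000.0 * (500.0 / p) ** 0.25

    num, den = [], []
    for u in range(n_units):
        params = _draw_mf_params(["BT", "LLB", "SLB"][u % 3], rng)
        params["pv_slope"] = float(rng.uniform(0.7, 1.1))
        params["peak_at_500"] = float(rng.uniform(200.0, 280.0))
        lam0 = mf_intensity(params, pv0, tradeoff(pv0), grid)
        h = 5.0
        g = (mf_intensity(params, pv0 + h, tradeoff(pv0 + h), grid)
             - mf_intensity(params, pv0 - h, tradeoff(pv0 - h), grid)) / (2 * h)
        # per-bin pedestal keeps the intensity non-negative over the whole
        # PV range while adding as little Poisson noise as possible; it is
        # part of R0(t), so the model stays exactly linear in dPV
        ped = np.maximum(0.0, -np.minimum(lam0 + (pv.min() - pv0) * g,
                                          lam0 + (pv.max() - pv0) * g))
        trains = [
            sample_spikes(np.maximum(lam0 + ped + (p - pv0) * g, 0.0), grid, rng)
            for p in pv
        ]
        pr = perievent_rate(trains, config.mf_grid_start_ms, config.mf_grid_stop_ms,
                            config.bin_ms, smoothing_sd_ms=5.0)
        _, drdz, _, _ = fit_unit_rate_model(pr.per_trial, pv[:, None], ("pv",))
        gs = gaussian_smooth(g, 5.0, config.bin_ms)
        top = np.argsort(np.abs(gs))[-int(np.ceil(0.1 * gs.size)):]
        num.append(np.mean((drdz[0][top] - gs[top]) ** 2))
        den.append(np.mean(gs[top] ** 2))
    return dict(
        relative_rmse=float(np.sqrt(np.sum(num) / np.sum(den))),
        n=n_units,
    )


def _session_units(seed: int, config: RunConfig):
    bundle, units, truth = generate_session(
        SessionConfig(n_trials=300, seed=seed), config, with_traces=False
    )
    cf = bundle.trials[bundle.trials["type"] == "centrifugal"]
    return bundle, units, truth, cf


def classifier_accuracy(seed: int, config: RunConfig = DEFAULT_CONFIG) -> dict:
    """MF and PC classification accuracy on labeled generator units."""
    mf_hits, pc_rates, pc_truth = [], [], []
    mean_dur = None
    for s in _child_seeds(seed, 2):
        bundle, units, truth, cf = _session_units(s, config)
        keep = set(cf["trial_index"].astype(int))
        mean_dur = float(cf["duration_ms"].mean())
        for rec in units:
            trains = [sp for ti, sp in zip(rec.trial_index, rec.spikes) if ti in keep]
            if rec.kind == "MF":
                pr = perievent_rate(trains, config.mf_grid_start_ms,
                                    config.mf_grid_stop_ms, config.bin_ms)
                mf_hits.append(classify_mf_unit(pr, config) == rec.class_label)
            else:
                pr = perievent_rate(trains, config.mf_grid_start_ms,
                                    config.mf_grid_stop_ms, config.bin_ms,
                                    smoothing_sd_ms=config.ss_smoothing_sd_ms)
                pc_rates.append(pr.mean_rate)
                pc_truth.append(rec.class_label)
    X = np.array(pc_rates)
    # threshold labels feed the PCA+LDA refinement
    t = np.arange(config.mf_grid_start_ms, config.mf_grid_stop_ms,
                  config.bin_ms) + config.bin_ms / 2
    from .classify import PeriEventRate

    thr_labels = np.array([
        label_pc_by_threshold(
            PeriEventRate(time_ms=t, mean_rate=r, per_trial=r[None, :]),
            mean_dur, config,
        )
        for r in pc_rates
    ])
    pred, _ = classify_pc_pca_lda(X, thr_labels)
    pc_truth = np.array(pc_truth)
    return dict(
        mf_accuracy=float(np.mean(mf_hits)),
        pc_accuracy=float(np.mean(pred == pc_truth)),
        n=len(mf_hits) + len(pc_truth),
    )


def cs_on_recovery(seed: int, config: RunConfig = DEFAULT_CONFIG) -> dict:
    """Fraction of PCs whose CS-ON direction is recovered from CS rates."""
    hits = []
    for s in _child_seeds(seed, 3):
        bundle, units, truth, cf = _session_units(s, config)
        for rec in units:
            if rec.kind != "PC":
                continue
            cs = {int(ti): c for ti, c in zip(rec.trial_index, rec.cs_times)}
            est = estimate_cs_on_direction(cs, cf, config)
            hits.append(est == truth.cs_on_directions[rec.unit_id])
    return dict(recovery_rate=float(np.mean(hits)), n=len(hits))


def lffn_checks(seed: int) -> dict:
    """Feed-forward model exactness and planted-structure recovery."""
    rng = np.random.default_rng(seed)
    n_mf, n_pc, T = 20, 12, 300
    X = rng.standard_normal((n_mf, T))
    dX = {"pv": rng.standard_normal((n_mf, T))}
    A = rng.standard_normal((n_pc, n_mf))
    Y, dY = A @ X, {"pv": A @ dX["pv"]}
    exact = LinearFeedforwardModel(cov=np.array([[2.0]]), alpha=0.0).fit(X, Y, dX, dY)
    exact_err = float(np.abs(exact.weights_ - A).max())

    Y2 = Y + 0.3 * rng.standard_normal(Y.shape)
    ols = LinearFeedforwardModel(cov=None, alpha=0.0).fit(X, Y2)
    oracle = np.linalg.solve(X @ X.T, X @ Y2.T).T
    ols_err = float(np.abs(ols.weights_ - oracle).max())

    A3 = rng.standard_normal((n_pc, 3)) @ rng.standard_normal((3, n_mf))
    res = communication_subspace(X, None, A3 @ X, None, None, ranks=[1, 2, 3, 4])
    losses = {r: res[r]["loss"] for r in (1, 2, 3, 4)}
    elbow = min((r for r in (1, 2, 3, 4)
                 if losses[r] < 1e-6 * max(losses[1], 1e-30)), default=4)

    # PC structure driven by MF components 6-15 (low-variance directions)
    t = np.linspace(0, 1, 400)
    basis = np.array([np.sin(2 * np.pi * (k + 1) * t) for k in range(30)])
    scales = np.concatenate([np.full(5, 10.0), np.full(10, 1.0), np.full(15, 0.05)])
    U = np.linalg.qr(rng.standard_normal((30, 30)))[0]
    Xp = (U * scales) @ basis
    Ap = rng.standard_normal((12, 30)) @ (U[:, 5:15] @ U[:, 5:15].T)
    Yp = Ap @ Xp
    mp = LinearFeedforwardModel(cov=None, alpha=0.0).fit(Xp, Yp)
    r2 = manifold_limited_prediction(mp, Xp, None, Yp, d_grid=[5, 15, 30])
    return dict(
        exact_recovery_error=exact_err,
        ols_oracle_error=ols_err,
        rank_elbow=int(elbow),
        dmf_r2_below_planted=float(r2[5]),
        dmf_r2_at_planted=float(r2[15]),
        n=n_mf,
    )


def stats_calibration(seed: int, n_null: int = 2000, n_power: int = 100) -> dict:
    """Jackknife exactness, t-test type-I calibration, and power of the
    early/late Wilcoxon procedure on the planted ~10% PV drift."""
    rng = np.random.default_rng(seed)
    x = list(rng.standard_normal(30))
    rep = jackknife_mean_sem(np.mean, x)
    sem_ratio = float(rep.sem / (np.std(x, ddof=1) / np.sqrt(len(x))))

    a = rng.standard_normal((n_null, 20))
    b = rng.standard_normal((n_null, 20))
    p = sps.ttest_ind(a, b, axis=1).pvalue
    type1 = float(np.mean(p < 0.05))

    from .behavior import compare_early_late

    hits = 0
    for s in _child_seeds(seed + 1, n_power):
        kin = generate_kinematics_sequence(SessionConfig(seed=s))
        cf = kin[kin["type"] == "centrifugal"]
        report = compare_early_late(cf, measures=("pv",)).set_index("measure")
        hits += report.loc["pv", "p"] < 0.05
    return dict(
        jackknife_sem_ratio=sem_ratio,
        t_test_type1_rate=type1,
        wilcoxon_drift_power=hits / n_power,
        n=n_null,
    )


# ----------------------------------------------------------------------
# end-to-end complex-spike conditioned ordering
# ----------------------------------------------------------------------

def cs_ordering_once(seed: int, config: RunConfig = DEFAULT_CONFIG) -> dict:
    """One session: CS-conditioned slope angles and their one-sided tests."""
    from .pipeline import _grid, _unit_rates

    cfg = SessionConfig(
        n_trials=400, seed=seed, direction_schedule="centrifugal_only",
        contingent_pv_gain=0.05, contingent_duration_gain=0.10,
        contingent_pv_coding_gain=0.5, contingent_duration_coding_gain=1.0,
        n_mf_bt=0, n_mf_llb=0, n_mf_slb=0,
        n_pc_burst=18, n_pc_pause=16, n_pc_burst_pause=9, n_pc_pause_burst=5,
    )
    bundle, _, _ = generate_session(cfg, config, with_traces=False)
    cf, rates, ev = _unit_rates(bundle, config, "PC", config.ss_smoothing_sd_ms)
    cs_on = {uid: estimate_cs_on_direction(d["cs"], cf, config)
             for uid, d in ev.items()}
    cs_ev = {u: d["cs"] for u, d in ev.items()}
    pools = {
        cond.error_type: pool_simulated_error_trials(cs_on, cs_ev, cf, cond, config)
        for cond in (CSCondition("outward"), CSCondition("inward"),
                     CSCondition("none"))
    }
    comp = conditioned_manifold_comparison(rates, cf, pools, _grid(config), config)
    return dict(
        angles=comp.angles,
        p=dict(zip(comp.tests["pair"], comp.tests["p"])),
    )


def cs_ordering_experiment(
    seed: int, n_seeds: int = 50, config: RunConfig = DEFAULT_CONFIG
) -> dict:
    """Fraction of sessions reproducing the error-type-dependent slope-angle
    ordering (inward > no-CS > outward) with one-sided p < 0.05 on every
    pairwise jackknife comparison."""
    good, angle_rows = 0, []
    for s in _child_seeds(seed, n_seeds):
        res = cs_ordering_once(s, config)
        a = res["angles"]
        ordered = a["inward"] > a["none"] > a["outward"]
        significant = all(p < 0.05 for p in res["p"].values())
        good += ordered and significant
        angle_rows.append(a)
    angles = pd.DataFrame(angle_rows)
    return dict(
        ordering_rate=good / n_seeds,
        mean_angles={k: float(angles[k].mean()) for k in angles},
        n=n_seeds,
    )
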