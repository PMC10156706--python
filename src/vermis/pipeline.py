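"""Stage-by-stage pipeline driver.

Stages run in order (simulate -> behavior -> classify -> fit-rates ->
manifolds -> cs-analysis -> lffn -> report) inside one results directory;
each stage persists its outputs as delimited tables / HDF5 containers plus
a config snapshot, so later stages (and re-runs) can pick up from disk.
Runs are deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import classify as cls
from .config import RunConfig, DEFAULT_CONFIG
from .cs_plasticity import (
    CSCondition,
    conditioned_manifold_comparison,
    estimate_cs_on_direction,
    pool_simulated_error_trials,
)
from .io import (
    SessionBundle,
    events_by_unit,
    load_matrices,
    read_bundle,
    save_matrices,
    write_bundle,
)
from .lffn import LinearFeedforwardModel, predict_and_score
from .manifolds import PopulationManifold, manifold_size, rotation_speed
from .rate_models import PopulationRateModel, kinematic_grid
from .synth import SessionConfig, generate_session

log = logging.getLogger("vermis")

STAGES = (
    "simulate",
    "behavior",
    "classify",
    "fit-rates",
    "manifolds",
    "cs-analysis",
    "lffn",
    "report",
)


class StageError(RuntimeError):
    """A pipeline stage failed or its upstream artifact is missing."""


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise StageError(
            f"stage {needed_by!r} requires output of stage {stage!r}: missing {path}"
        )
    return path


def _grid(config: RunConfig) -> np.ndarray:
    edges = np.arange(
        config.mf_grid_start_ms, config.mf_grid_stop_ms + config.bin_ms, config.bin_ms
    )
    return edges[:-1] + config.bin_ms / 2.0


def _unit_rates(bundle: SessionBundle, config: RunConfig, kind: str, sd_ms: float):
    """Per-unit per-trial rate matrices over the centrifugal trials."""
    cf = bundle.centrifugal_trials().sort_values("trial_index")
    order = cf["trial_index"].astype(int).tolist()
    ev = events_by_unit(bundle, kind)
    rates = {}
    for uid, d in ev.items():
        trains = [d["spikes"].get(t, np.empty(0)) for t in order]
        pr = cls.perievent_rate(
            trains,
            config.mf_grid_start_ms,
            config.mf_grid_stop_ms,
            config.bin_ms,
            smoothing_sd_ms=sd_ms,
        )
        rates[uid] = pr.per_trial
    return cf, rates, ev


def run_stage(stage: str, outdir: Path, config: RunConfig,
              session_cfg: SessionConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle_dir = outdir / "bundle"

    if stage == "simulate":
        scfg = session_cfg or SessionConfig(seed=config.seed)
        bundle, _, _ = generate_session(scfg, config)
        write_bundle(bundle, bundle_dir)

    elif stage == "behavior":
        bundle = read_bundle(_require(bundle_dir, "simulate", stage))
        trials = beh.extract_trials(bundle, config)
        trials.to_csv(outdir / "behavior_trials.tsv", sep="\t", index=False)
        cf = trials[trials["type"] == "centrifugal"]
        if len(cf) >= 2 * config.early_late_n:
            beh.compare_early_late(cf, config=config).to_csv(
                outdir / "early_late.tsv", sep="\t", index=False
            )

    elif stage == "classify":
        bundle = read_bundle(_require(bundle_dir, "simulate", stage))
        cf = bundle.centrifugal_trials()
        mean_dur = float(cf["duration_ms"].mean())
        rows = []
        for kind, sd in (("MF", 0.0), ("PC", config.ss_smoothing_sd_ms)):
            _, rates, ev = _unit_rates(bundle, config, kind, sd)
            t = _grid(config)
            for uid, per_trial in rates.items():
                pr = cls.PeriEventRate(
                    time_ms=t, mean_rate=per_trial.mean(axis=0),
                    per_trial=per_trial, smoothing_sd_ms=sd,
                )
                if kind == "MF":
                    label = cls.classify_mf_unit(pr, config)
                    bounds = cls.detect_modulation_bounds(pr, mean_dur, config)
                else:
                    label = cls.label_pc_by_threshold(pr, mean_dur, config)
                    bounds = None
                rows.append(
                    dict(
                        unit_id=uid, kind=kind, class_label=label,
                        onset_ms=bounds[0] if bounds else np.nan,
                        offset_ms=bounds[1] if bounds else np.nan,
                    )
                )
        pd.DataFrame(rows).to_csv(outdir / "unit_classes.tsv", sep="\t", index=False)

    elif stage == "fit-rates":
        bundle = read_bundle(_require(bundle_dir, "simulate", stage))
        t = _grid(config)
        for kind in ("MF", "PC"):
            cf, rates, _ = _unit_rates(bundle, config, kind, config.rate_smoothing_sd_ms)
            include = (
                config.include_mf_units if kind == "MF" else config.include_pc_units
            )
            uids = sorted(rates)
            if include is not None:
                uids = [u for u in uids if u in include]
            z = cf["pv"].to_numpy(float)[:, None]
            model = PopulationRateModel(
                param_names=("pv",), baseline_window=config.baseline_window, time_ms=t
            ).fit([rates[u] for u in uids], [z] * len(uids))
            save_matrices(
                outdir / f"rate_model_{kind.lower()}.h5",
                {
                    "model": dict(
                        R0=model.R0_, dRdz_pv=model.dRdz_["pv"], z0=model.z0_,
                        time_ms=t,
                    ),
                    "units": dict(ids=np.array(uids, dtype="S")),
                },
            )

    elif stage == "manifolds":
        rows = []
        for kind in ("mf", "pc"):
            path = _require(outdir / f"rate_model_{kind}.h5", "fit-rates", stage)
            m = load_matrices(path)["model"]
            t = m["time_ms"]
            man = PopulationManifold(variance_threshold=config.variance_threshold).fit(
                m["R0"], {"pv": m["dRdz_pv"]}
            )
            bundle = read_bundle(bundle_dir)
            grid = kinematic_grid(
                bundle.centrifugal_trials(), config.pv_grid_points, "pv",
                percentiles=config.pv_grid_percentiles,
            )
            pv0 = float(m["z0"].mean())
            for _, row in grid.iterrows():
                P = man.evaluate_trajectory({"pv": row["pv"] - pv0})
                xy = P[:2].T
                speed, t34 = rotation_speed(xy, t)
                rows.append(
                    dict(
                        population=kind, pv=row["pv"], K=man.K_,
                        size=manifold_size(xy), speed=speed, t34=t34,
                    )
                )
            save_matrices(
                outdir / f"manifold_{kind}.h5",
                {"manifold": dict(W=man.W_, P=man.P_,
                                  dPdz_pv=man.dPdz_["pv"], dWdz_pv=man.dWdz_["pv"],
                                  explained=man.explained_variance_ratio_)},
            )
        pd.DataFrame(rows).to_csv(outdir / "manifold_metrics.tsv", sep="\t", index=False)

    elif stage == "cs-analysis":
        bundle = read_bundle(_require(bundle_dir, "simulate", stage))
        cf, rates, ev = _unit_rates(bundle, config, "PC", config.ss_smoothing_sd_ms)
        cs_on = {
            uid: estimate_cs_on_direction(d["cs"], cf, config) for uid, d in ev.items()
        }
        pools = {
            cond.error_type: pool_simulated_error_trials(
                cs_on, {u: d["cs"] for u, d in ev.items()}, cf, cond, config
            )
            for cond in (
                CSCondition("outward", config.cs_window_early),
                CSCondition("inward", config.cs_window_early),
                CSCondition("none", config.cs_window_early),
            )
        }
        comp = conditioned_manifold_comparison(
            rates, cf, pools, _grid(config), config
        )
        comp.metrics.to_csv(outdir / "cs_metrics.tsv", sep="\t", index=False)
        comp.tests.assign(
            **{f"angle_{k}": v for k, v in comp.angles.items()}
        ).to_csv(outdir / "cs_tests.tsv", sep="\t", index=False)

    elif stage == "lffn":
        mf = load_matrices(_require(outdir / "rate_model_mf.h5", "fit-rates", stage))["model"]
        pc = load_matrices(_require(outdir / "rate_model_pc.h5", "fit-rates", stage))["model"]
        bundle = read_bundle(bundle_dir)
        pv = bundle.centrifugal_trials()["pv"].to_numpy(float)
        cov = np.atleast_2d(np.var(pv, ddof=1))
        model = LinearFeedforwardModel(cov=cov, alpha="aic").fit(
            mf["R0"], pc["R0"], dXdz={"pv": mf["dRdz_pv"]}, dYdz={"pv": pc["dRdz_pv"]}
        )
        score = predict_and_score(
            model, mf["R0"], pc["R0"], {"pv": mf["dRdz_pv"]}, {"pv": pc["dRdz_pv"]},
            bootstrap_reps=config.bootstrap_reps, seed=config.seed,
        )
        save_matrices(outdir / "lffn.h5", {"model": dict(weights=model.weights_,
                                                         alpha=model.alpha_)})
        pd.DataFrame(
            dict(unit=np.arange(score["r2"].size), r2=score["r2"])
        ).to_csv(outdir / "lffn_r2.tsv", sep="\t", index=False)

    elif stage == "report":
        summary = {}
        for name in ("early_late", "manifold_metrics", "cs_tests", "lffn_r2"):
            p = outdir / f"{name}.tsv"
            if p.exists():
                summary[name] = pd.read_csv(p, sep="\t").to_dict(orient="records")
        (outdir / "report.json").write_text(json.dumps(summary, indent=1, default=str))

    else:
        raise StageError(f"unknown stage {stage!r}")

    config.to_yaml(outdir / "config_snapshot.yaml")


def run_pipeline(
    outdir,
    config: RunConfig = DEFAULT_CONFIG,
    session_cfg: SessionConfig | None = None,
    stages=STAGES,
) -> Path:
    """Run the requested stages in order; halts on the first failure."""
    outdir = Path(outdir)
    for stage in stages:
        if stage not in STAGES:
            raise StageError(f"unknown stage {stage!r}")
        log.info("running stage %s", stage)
        try:
            run_stage(stage, outdir, config, session_cfg)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return outdir
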