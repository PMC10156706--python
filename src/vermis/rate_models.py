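"""Per-unit linear kinematic rate models and pseudo-populations.

Each unit's baseline-subtracted firing rate is modeled as a
kinematics-independent component plus kinematics-dependent derivatives,

    R_n(t, z) = R0_n(t) + sum_z (z - z0) dR_n/dz (t),

fitted by time-binwise multivariate linear regression of per-trial rates
on the kinematic deviations (peak velocity and/or duration).  Evaluating
all fitted units on a common kinematic grid yields a pseudo-population
response in which every unit contributes equally at every grid point, as
if recorded simultaneously.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import RunConfig, DEFAULT_CONFIG

log = logging.getLogger("vermis")

__all__ = [
    "PopulationRateModel",
    "PseudoPopulation",
    "fit_unit_rate_model",
    "assemble_pseudopopulation",
    "kinematic_grid",
    "predict_population_summary",
    "validate_split",
]

_COND_WARN = 1e4
_COND_ERR = 1e10


def fit_unit_rate_model(
    rates: np.ndarray, z: np.ndarray, param_names: tuple
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Time-binwise least squares of one unit's rates on kinematic deviations.

    ``rates``: (n_trials, T) baseline-subtracted rates; ``z``: (n_trials, p).
    Returns (R0(t), dRdz (p, T), z0, diagnostics).  The intercept is R0 and
    the coefficient of each delta-z column the kinematic derivative.
    """
    rates = np.asarray(rates, float)
    z = np.atleast_2d(np.asarray(z, float))
    if z.shape[0] != rates.shape[0]:
        z = z.T
    n = rates.shape[0]
    if n < 10:
        raise ValueError(f"need >= 10 trials to fit a rate model, got {n}")
    z0 = z.mean(axis=0)
    dz = z - z0
    sd = dz.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0.0:
            raise ValueError(
                f"kinematic parameter {param_names[j]!r} is constant across "
                "trials; the design is rank deficient"
            )
    design = np.column_stack([np.ones(n), dz])
    cond = np.linalg.cond(design / np.linalg.norm(design, axis=0))
    if cond > _COND_ERR:
        raise ValueError(
            f"rank-deficient design (condition {cond:.2g}); parameters "
            f"{param_names} are collinear"
        )
    if cond > _COND_WARN:
        warnings.warn(
            f"ill-conditioned kinematic design (condition {cond:.2g}); "
            f"parameters {param_names} are nearly collinear (velocity-"
            "duration tradeoff); consider a single-parameter model",
            UserWarning,
        )
    coef, _, _, _ = np.linalg.lstsq(design, rates, rcond=None)
    r0 = coef[0]
    drdz = coef[1:]
    resid = rates - design @ coef
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((rates - rates.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    dof = max(n - design.shape[1], 1)
    se = np.sqrt(ss_res / dof)
    return r0, drdz, z0, dict(r2=r2, se=se, condition=float(cond))


class PopulationRateModel(BaseEstimator):
    """Linear kinematic rate models for a population of serially recorded
    units, sharing a time grid and kinematic parameter set.

    Parameters
    ----------
    param_names : tuple of {"pv", "duration"}
        Kinematic parameters entering the model.
    baseline_window : (lo, hi) or None
        Pre-saccadic window (ms) whose per-trial mean is subtracted from
        each unit's rates before fitting; None if rates arrive
        baseline-subtracted.
    """

    def __init__(self, param_names=("pv",), baseline_window=None, time_ms=None):
        self.param_names = param_names
        self.baseline_window = baseline_window
        self.time_ms = time_ms

    def fit(self, unit_rates: list, unit_z: list):
        """Fit every unit.

        ``unit_rates[i]`` is the (n_trials_i, T) rate matrix of unit i;
        ``unit_z[i]`` the matching (n_trials_i, p) kinematics.
        """
        if len(unit_rates) != len(unit_z):
            raise ValueError("unit_rates and unit_z must have equal length")
        T = np.asarray(unit_rates[0]).shape[1]
        r0s, deriv, z0s, diags = [], [], [], []
        for rates, z in zip(unit_rates, unit_z):
            rates = np.asarray(rates, float)
            if rates.shape[1] != T:
                raise ValueError("all units must share the same time grid")
            if self.baseline_window is not None and self.time_ms is not None:
                lo, hi = self.baseline_window
                mask = (np.asarray(self.time_ms) >= lo) & (np.asarray(self.time_ms) < hi)
                rates = rates - rates[:, mask].mean(axis=1, keepdims=True)
            r0, drdz, z0, diag = fit_unit_rate_model(rates, z, tuple(self.param_names))
            r0s.append(r0)
            deriv.append(drdz)
            z0s.append(z0)
            diags.append(diag)
        self.R0_ = np.stack(r0s)                       # (N, T)
        deriv = np.stack(deriv)                        # (N, p, T)
        self.dRdz_ = {
            name: deriv[:, j, :] for j, name in enumerate(self.param_names)
        }
        self.z0_ = np.stack(z0s)                       # (N, p)
        self.diagnostics_ = diags
        self.n_units_ = len(unit_rates)
        self.n_timepoints_ = T
        return self

    def evaluate(self, z) -> np.ndarray:
        """Population rates (N, T) at kinematics ``z`` (mapping name -> value).

        Each unit's deviation is taken from its own session mean z0.
        """
        check_is_fitted(self, "R0_")
        R = self.R0_.copy()
        for j, name in enumerate(self.param_names):
            if name not in z:
                raise KeyError(f"missing kinematic parameter {name!r}")
            dz = np.asarray(z[name], float) - self.z0_[:, j]
            R = R + dz[:, None] * self.dRdz_[name]
        extra = set(z) - set(self.param_names)
        if extra:
            raise KeyError(f"unknown kinematic parameters {sorted(extra)}")
        return R


@dataclass
class PseudoPopulation:
    """Rate model evaluated on a kinematic grid: (n_grid, N, T) tensor."""

    model: PopulationRateModel
    grid: pd.DataFrame                 # one row per grid point
    rates: np.ndarray                  # (n_grid, N, T)
    time_ms: np.ndarray | None = None


def kinematic_grid(
    trials: pd.DataFrame,
    n_points: int = 5,
    vary: str = "pv",
    isolate: bool = False,
    percentiles: tuple = (10.0, 90.0),
) -> pd.DataFrame:
    """Kinematic grid spanning the central percentile range of ``vary``.

    With ``isolate`` the other parameter is clamped at its mean (isolated
    variation); otherwise it co-varies following the empirical linear
    regression on ``vary`` (correlated variation).
    """
    other = "duration_ms" if vary == "pv" else "pv"
    vals = np.linspace(
        *np.percentile(trials[vary].to_numpy(float), percentiles), n_points
    )
    if isolate:
        ov = np.full(n_points, trials[other].mean())
    else:
        b, a = np.polyfit(trials[vary], trials[other], 1)
        ov = a + b * vals
    return pd.DataFrame({vary: vals, other: ov})


def assemble_pseudopopulation(
    model: PopulationRateModel, grid: pd.DataFrame
) -> PseudoPopulation:
    """Evaluate the fitted model at every kinematic grid point."""
    check_is_fitted(model, "R0_")
    cols = {"pv": "pv", "duration": "duration_ms"}
    tensors = []
    for _, row in grid.iterrows():
        z = {}
        for name in model.param_names:
            col = cols.get(name, name)
            col = col if col in grid.columns else name
            z[name] = float(row[col])
        tensors.append(model.evaluate(z))
    return PseudoPopulation(
        model=model, grid=grid.reset_index(drop=True), rates=np.stack(tensors),
        time_ms=np.asarray(model.time_ms) if model.time_ms is not None else None,
    )


def predict_population_summary(
    pop: PseudoPopulation, config: RunConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Peak rate and burst duration of the population-mean trace per grid
    point; NaNs where no modulation crosses threshold."""
    from .classify import PeriEventRate, detect_modulation_bounds

    if pop.time_ms is None:
        raise ValueError("pseudo-population lacks a time grid")
    rows = []
    for g in range(pop.rates.shape[0]):
        mean_trace = pop.rates[g].mean(axis=0)
        rate = PeriEventRate(
            time_ms=pop.time_ms, mean_rate=mean_trace, per_trial=mean_trace[None, :]
        )
        dur = pop.grid.loc[g, "duration_ms"] if "duration_ms" in pop.grid else 60.0
        try:
            bounds = detect_modulation_bounds(rate, float(dur), config)
        except ValueError:
            bounds = None
        rows.append(
            dict(
                grid_index=g,
                peak_rate=float(mean_trace.max()),
                peak_time_ms=float(pop.time_ms[int(np.argmax(mean_trace))]),
                burst_onset_ms=bounds[0] if bounds else np.nan,
                burst_offset_ms=bounds[1] if bounds else np.nan,
                burst_duration_ms=(bounds[1] - bounds[0]) if bounds else np.nan,
            )
        )
    return pd.DataFrame(rows)


def validate_split(
    rates: np.ndarray, z: np.ndarray, param_names: tuple = ("pv",), seed: int = 0
) -> tuple[dict, dict]:
    """Half-split validation of one unit's rate model.

    Trials are split into two equal halves (odd counts drop the last
    trial, logged); the model is fitted on the train half and scored by
    the R^2 between the predicted and observed mean rate of the test half.
    """
    rates = np.asarray(rates, float)
    z = np.atleast_2d(np.asarray(z, float))
    if z.shape[0] != rates.shape[0]:
        z = z.T
    n = rates.shape[0]
    if n < 20:
        raise ValueError("need >= 20 trials for split validation")
    if n % 2:
        log.info("validate_split: odd trial count %d, dropping last trial", n)
        rates, z = rates[:-1], z[:-1]
        n -= 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train, test = perm[: n // 2], perm[n // 2 :]
    r0, drdz, z0, diag = fit_unit_rate_model(rates[train], z[train], param_names)
    dz_test = z[test] - z0
    pred_mean = r0 + dz_test.mean(axis=0) @ drdz
    obs_mean = rates[test].mean(axis=0)
    ss_res = ((obs_mean - pred_mean) ** 2).sum()
    ss_tot = ((obs_mean - obs_mean.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    model = dict(R0=r0, dRdz=drdz, z0=z0, diagnostics=diag)
    return model, dict(test_r2=float(r2), n_train=len(train), n_test=len(test))
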