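"""Linear feed-forward network (LFFN) from mossy-fiber to Purkinje-cell
rates, with a kinematics-weighted loss, LASSO/AIC regularization,
manifold-dimension-limited prediction and a reduced-rank (communication
subspace) variant.

The weight matrix T minimizes

    E(T) = ||Y - T X||^2
         + sum_{z,z'} Cov[z,z'] (dY/dz - T dX/dz) . (dY/dz' - T dX/dz'),

where (X, dX/dz) and (Y, dY/dz) are the kinematics-independent and
kinematics-dependent rate-model components of the input and output
populations and Cov is the empirical covariance of the trial kinematics
(z taken Gaussian).  Factoring Cov by its symmetric square root turns the
loss into ordinary least squares on the column-augmented design
[X | sum_z M_kz dX/dz], solved per output unit with an optional L1
penalty whose strength is chosen by AIC.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import orthogonal_procrustes
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso, LassoLarsIC
from sklearn.utils.validation import check_is_fitted

from .manifolds import PopulationManifold
from .stats import bootstrap_gof

__all__ = [
    "LinearFeedforwardModel",
    "augment_design",
    "fit_lffn",
    "predict_and_score",
    "manifold_limited_prediction",
    "communication_subspace",
    "variance_spectrum",
]


def _cov_sqrt(cov: np.ndarray) -> np.ndarray:
    cov = np.atleast_2d(np.asarray(cov, float))
    if not np.allclose(cov, cov.T):
        raise ValueError("Cov[z,z'] must be symmetric")
    w, E = np.linalg.eigh(cov)
    if np.any(w < -1e-10 * max(w.max(), 1.0)):
        raise ValueError("Cov[z,z'] must be positive semidefinite")
    w = np.clip(w, 0.0, None)
    return (E * np.sqrt(w)) @ E.T


def augment_design(X: np.ndarray, dXdz: dict, cov: np.ndarray | None,
                   param_order: tuple) -> np.ndarray:
    """Column-augmented design [X | sum_z M_kz dX/dz] with M = Cov^(1/2)."""
    X = np.asarray(X, float)
    blocks = [X]
    if cov is not None and dXdz:
        M = _cov_sqrt(cov)
        D = [np.asarray(dXdz[name], float) for name in param_order]
        for k in range(M.shape[0]):
            blocks.append(sum(M[k, z] * D[z] for z in range(len(D))))
    return np.concatenate(blocks, axis=1)


class LinearFeedforwardModel(BaseEstimator, RegressorMixin):
    """MF -> PC linear mapping under the kinematics-weighted loss.

    Parameters
    ----------
    cov : (p, p) array or None
        Empirical covariance of the kinematic parameters; None (or zeros)
        reduces the loss to plain least squares on the rates.
    alpha : "aic", float, or array of floats
        L1 penalty.  "aic" selects the penalty along the LARS path by AIC
        per output unit; an array is an explicit grid searched by AIC;
        0 disables the penalty (exact least squares).
    param_order : tuple
        Order of the kinematic parameters in the derivative dicts.
    """

    def __init__(self, cov=None, alpha="aic", param_order=("pv",)):
        self.cov = cov
        self.alpha = alpha
        self.param_order = param_order

    def fit(self, X, Y, dXdz: dict | None = None, dYdz: dict | None = None):
        dXdz = dXdz or {}
        dYdz = dYdz or {}
        Xa = augment_design(X, dXdz, self.cov, self.param_order)
        Ya = augment_design(Y, dYdz, self.cov, self.param_order)
        if Xa.shape[1] != Ya.shape[1]:
            raise ValueError("input and output designs have mismatched widths")
        A = Xa.T                               # (samples, n_mf)
        B = Ya.T
        alpha = self.alpha
        if isinstance(alpha, (list, tuple, np.ndarray)) and len(alpha) == 0:
            raise ValueError("empty penalty grid")
        if alpha == "aic" if isinstance(alpha, str) else False:
            coefs, alphas = [], []
            for j in range(B.shape[1]):
                est = LassoLarsIC(criterion="aic", fit_intercept=False).fit(A, B[:, j])
                coefs.append(est.coef_)
                alphas.append(est.alpha_)
            self.weights_ = np.stack(coefs)
            self.alpha_ = np.array(alphas)
        elif np.isscalar(alpha) and float(alpha) == 0.0:
            W, _, _, _ = np.linalg.lstsq(A, B, rcond=None)
            self.weights_ = W.T
            self.alpha_ = np.zeros(B.shape[1])
        else:
            grid = np.atleast_1d(np.asarray(alpha, float))
            n = A.shape[0]
            coefs, alphas = [], []
            for j in range(B.shape[1]):
                best = (np.inf, None, None)
                for a in grid:
                    if a == 0.0:
                        w, _, _, _ = np.linalg.lstsq(A, B[:, j], rcond=None)
                    else:
                        w = Lasso(alpha=float(a), fit_intercept=False,
                                  max_iter=5000).fit(A, B[:, j]).coef_
                    rss = float(((B[:, j] - A @ w) ** 2).sum())
                    df = int(np.count_nonzero(w))
                    aic = n * np.log(max(rss, 1e-300) / n) + 2 * df
                    if aic < best[0]:
                        best = (aic, w, a)
                coefs.append(best[1])
                alphas.append(best[2])
            self.weights_ = np.stack(coefs)
            self.alpha_ = np.array(alphas)
        self.loss_ = float(((Ya - self.weights_ @ Xa) ** 2).sum())
        self._shapes = (np.asarray(X).shape, np.asarray(Y).shape)
        return self

    def predict(self, X, dXdz: dict | None = None):
        """Predicted output rates (and derivatives when given)."""
        check_is_fitted(self, "weights_")
        Y = self.weights_ @ np.asarray(X, float)
        if dXdz is None:
            return Y
        return Y, {k: self.weights_ @ np.asarray(v, float) for k, v in dXdz.items()}

    def objective(self, T, X, Y, dXdz=None, dYdz=None) -> float:
        """Eq-style loss of an arbitrary weight matrix (for spot checks)."""
        Xa = augment_design(X, dXdz or {}, self.cov, self.param_order)
        Ya = augment_design(Y, dYdz or {}, self.cov, self.param_order)
        return float(((Ya - np.asarray(T) @ Xa) ** 2).sum())


def fit_lffn(X, dXdz, Y, dYdz, cov, alpha="aic", param_order=("pv",)):
    """Fit the feed-forward model (module-level convenience wrapper)."""
    model = LinearFeedforwardModel(cov=cov, alpha=alpha, param_order=param_order)
    return model.fit(X, Y, dXdz=dXdz, dYdz=dYdz)


def predict_and_score(
    model: LinearFeedforwardModel,
    X, Y, dXdz=None, dYdz=None,
    bootstrap_reps: int = 500,
    seed: int = 0,
):
    """Per-output-unit R^2 under the augmented design, with a bootstrap
    over time points (mean +- SEM, 500 repetitions)."""
    check_is_fitted(model, "weights_")
    Xa = augment_design(X, dXdz or {}, model.cov, model.param_order)
    Ya = augment_design(Y, dYdz or {}, model.cov, model.param_order)
    pred = model.weights_ @ Xa
    resid2 = (Ya - pred) ** 2
    denom = ((Ya - Ya.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    r2 = np.full(Ya.shape[0], np.nan)
    ok = denom > 0
    r2[ok] = 1.0 - resid2[ok].sum(axis=1) / denom[ok]
    if not ok.all():
        import warnings

        warnings.warn("zero-variance target rows; R^2 undefined (NaN)", UserWarning)
    # bootstrap over time points of the pooled per-timepoint score
    with np.errstate(invalid="ignore", divide="ignore"):
        per_time = 1.0 - resid2[ok].sum(axis=0) / (
            ((Ya[ok] - Ya[ok].mean(axis=1, keepdims=True)) ** 2).sum(axis=0)
        )
    boot = bootstrap_gof(per_time, reps=bootstrap_reps, seed=seed)
    return dict(r2=r2, bootstrap=boot)


def manifold_limited_prediction(
    model: LinearFeedforwardModel,
    X, dXdz, Y,
    d_grid,
    n_latent: int = 2,
) -> dict:
    """Goodness of the predicted PC manifold when inputs are approximated
    by a d_MF-dimensional MF manifold.

    For each d in ``d_grid`` the MF rates (and derivatives) are
    reconstructed from the top-d MF principal components, pushed through
    the fitted weights, a PC manifold is fitted to the predictions, and
    its first ``n_latent`` latent trajectories are scored (R^2 after
    orthogonal Procrustes alignment with scaling) against the manifold of
    the observed PC rates.
    """
    check_is_fitted(model, "weights_")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n_mf = X.shape[0]
    d_grid = [int(d) for d in d_grid]
    if max(d_grid) > n_mf:
        raise ValueError(f"d_MF={max(d_grid)} exceeds the {n_mf} MF units")
    mf_man = PopulationManifold(n_components=n_mf).fit(X)
    pc_ref = PopulationManifold(n_components=n_latent).fit(Y)
    P_ref = pc_ref.P_
    ss_tot = ((P_ref - P_ref.mean(axis=1, keepdims=True)) ** 2).sum()
    out = {}
    for d in d_grid:
        W_d = mf_man.W_[:, :d]
        X_d = W_d @ (W_d.T @ X)
        Y_hat = model.weights_ @ X_d
        try:
            pc_hat = PopulationManifold(n_components=n_latent).fit(Y_hat)
        except ValueError:
            out[d] = -np.inf
            continue
        P_hat = pc_hat.P_
        Omega, scale = orthogonal_procrustes(P_hat.T, P_ref.T)
        norm2 = (P_hat**2).sum()
        s = scale / norm2 if norm2 > 0 else 0.0
        aligned = s * (P_hat.T @ Omega).T
        out[d] = float(1.0 - ((aligned - P_ref) ** 2).sum() / ss_tot)
    return out


def communication_subspace(
    X, dXdz, Y, dYdz, cov, ranks, param_order=("pv",)
) -> dict:
    """Reduced-rank regression under the kinematics-weighted loss.

    The full least-squares solution is truncated to rank r by projecting
    the fitted outputs onto their top-r principal subspace (the standard
    reduced-rank construction in the output metric).  Returns per-rank
    loss and per-output-unit R^2.
    """
    Xa = augment_design(X, dXdz or {}, cov, param_order)
    Ya = augment_design(Y, dYdz or {}, cov, param_order)
    W_full, _, _, _ = np.linalg.lstsq(Xa.T, Ya.T, rcond=None)
    T_full = W_full.T
    fitted = T_full @ Xa
    U, _, _ = np.linalg.svd(fitted, full_matrices=False)
    rmax = min(T_full.shape)
    denom = ((Ya - Ya.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    result = {}
    for r in ranks:
        r = int(r)
        if r > rmax:
            raise ValueError(f"rank {r} exceeds min dimension {rmax}")
        Ur = U[:, :r]
        T_r = Ur @ (Ur.T @ T_full)
        resid = Ya - T_r @ Xa
        loss = float((resid**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom > 0, 1.0 - (resid**2).sum(axis=1) / denom, np.nan)
        result[r] = dict(loss=loss, r2=r2, weights=T_r)
    return result


def variance_spectrum(X: np.ndarray, fit_range: tuple = (1, 10)) -> dict:
    """PCA eigenspectrum of a population (variance fractions) and the
    power-law exponent of its decay over a dimension range.

    The exponent b of fraction ~ 1/d^b is the negative slope of the
    log-log linear fit over dimensions ``fit_range`` (inclusive).
    """
    X = np.asarray(X, float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 units")
    s = np.linalg.svd(X - X.mean(axis=1, keepdims=True), compute_uv=False)
    frac = s**2 / (s**2).sum()
    lo, hi = int(fit_range[0]), int(fit_range[1])
    if hi > frac.size or lo < 1:
        raise ValueError(f"fit range {fit_range} outside available {frac.size} dims")
    d = np.arange(lo, hi + 1)
    slope, _ = np.polyfit(np.log(d), np.log(frac[lo - 1 : hi]), 1)
    return dict(fractions=frac, exponent=float(-slope), fit_range=(lo, hi))
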