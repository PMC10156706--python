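"""Population manifolds: PCA of the kinematics-independent rates, their
kinematic derivatives by first-order perturbation theory, and manifold
geometry/dynamics statistics.

The manifold of a population rate model is the rank-K factorization
R0 ~= W P_K obtained from an (uncentered) PCA across units, K chosen as the
smallest dimensionality capturing more than 85% of the cell-to-cell
variability.  How the latent trajectories move when a kinematic parameter
z deviates from its mean is predicted to first order by

    P_K -> P_K + sum_z dz dP_K/dz,
    dP_K/dz = W^T (dR/dz) + (dW/dz)^T (R0 - W P_K),

where dW/dz follows from eigenvector perturbation of the second-moment
matrix of R0 and captures how non-retained (>K) components rotate into the
manifold.  Trajectory geometry is summarized by the enclosed 2-D area
("manifold size"), the average rotation speed 270 deg / T_3/4, and the
slope angle of the (size, speed) relationship in control-normalized
coordinates.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import orthogonal_procrustes, qr, svdvals
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PopulationManifold",
    "fit_base_manifold",
    "procrustes_align",
    "manifold_size",
    "rotation_phase",
    "rotation_speed",
    "slope_angle",
    "align_cca",
    "encoding_dimensionality",
    "eigenvalue_stability",
]


def _fix_signs(W: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: largest-|loading| entry positive."""
    flip = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    flip[flip == 0] = 1.0
    return W * flip, P * flip[:, None]


class PopulationManifold(BaseEstimator, TransformerMixin):
    """Low-dimensional manifold of a population rate model.

    Parameters
    ----------
    variance_threshold : float
        K is the smallest dimensionality whose cumulative explained
        variance exceeds this fraction (ignored if ``n_components`` set).
    n_components : int or None
        Fixed dimensionality override.
    derivative_method : {"perturbation", "finite_difference"}
        How kinematic derivatives of the manifold are computed: analytic
        first-order eigenvector perturbation, or a symmetric-difference
        re-fit of the PCA at z0 +- h aligned to the base by orthogonal
        Procrustes.  Both agree to first order.
    """

    def __init__(
        self,
        variance_threshold: float = 0.85,
        n_components: int | None = None,
        derivative_method: str = "perturbation",
        fd_step: float | None = None,
        eig_gap_rtol: float = 1e-6,
    ):
        self.variance_threshold = variance_threshold
        self.n_components = n_components
        self.derivative_method = derivative_method
        self.fd_step = fd_step
        self.eig_gap_rtol = eig_gap_rtol

    # ------------------------------------------------------------------
    def fit(self, R0: np.ndarray, dRdz: dict | None = None):
        """Fit the base manifold of ``R0`` (N units x T time bins); if
        ``dRdz`` maps parameter names to (N, T) derivative matrices, the
        manifold derivatives are computed as well."""
        R0 = np.asarray(R0, float)
        if R0.ndim != 2 or R0.shape[0] < 3:
            raise ValueError("R0 must be (N >= 3, T)")
        if not np.any(R0):
            raise ValueError("zero-variance input")
        U, s, Vt = np.linalg.svd(R0, full_matrices=False)
        var = s**2
        self.explained_variance_ratio_ = var / var.sum()
        cum = np.cumsum(self.explained_variance_ratio_)
        if self.n_components is not None:
            K = int(self.n_components)
        else:
            K = int(np.searchsorted(cum, self.variance_threshold) + 1)
            K = min(K, s.size)
        if R0.shape[1] < K:
            raise ValueError("T must be >= K")
        W = U[:, :K]
        P = (s[:K, None] * Vt[:K])
        self.W_, self.P_ = _fix_signs(W, P)
        self.K_ = K
        self.singular_values_ = s
        self._U = U
        self._R0 = R0
        self.dPdz_: dict = {}
        self.dWdz_: dict = {}
        if dRdz is not None:
            self.compute_derivatives(dRdz)
        return self

    def transform(self, R: np.ndarray) -> np.ndarray:
        """Project population rates onto the fitted manifold (K, T)."""
        check_is_fitted(self, "W_")
        return self.W_.T @ np.asarray(R, float)

    # ------------------------------------------------------------------
    def compute_derivatives(self, dRdz: dict) -> None:
        """Kinematic derivatives dP/dz and dW/dz for each parameter."""
        check_is_fitted(self, "W_")
        for name, D in dRdz.items():
            D = np.asarray(D, float)
            if D.shape != self._R0.shape:
                raise ValueError(f"dRdz[{name!r}] must match R0's shape")
            if self.derivative_method == "perturbation":
                dW = self._dW_perturbation(D)
            elif self.derivative_method == "finite_difference":
                dW = self._dW_finite_difference(D)
            else:
                raise ValueError(f"unknown derivative_method {self.derivative_method!r}")
            resid = self._R0 - self.W_ @ self.P_
            self.dWdz_[name] = dW
            self.dPdz_[name] = self.W_.T @ D + dW.T @ resid

    def _dW_perturbation(self, D: np.ndarray) -> np.ndarray:
        """First-order eigenvector perturbation of C = R0 R0^T / T under
        the rate perturbation dz*D; mixing restricted to non-retained
        components (they are what rotates into the manifold)."""
        R0 = self._R0
        T = R0.shape[1]
        lam = self.singular_values_**2 / T              # descending
        V = self._U                                      # full eigenbasis
        dC = (D @ R0.T + R0 @ D.T) / T
        K = self.K_
        lam1 = lam[0] if lam.size else 1.0
        dW = np.zeros_like(self.W_)
        for k in range(K):
            num = V[:, K:].T @ dC @ (self.W_[:, k])
            denom = lam[k] - lam[K:]
            small = np.abs(denom) < self.eig_gap_rtol * lam1
            if small.any():
                warnings.warn(
                    "near-degenerate eigenvalue gap; regularizing the "
                    "perturbation denominator",
                    UserWarning,
                )
                denom = np.where(
                    small, np.sign(denom + 1e-300) * self.eig_gap_rtol * lam1, denom
                )
            dW[:, k] = V[:, K:] @ (num / denom)
        return dW

    def _dW_finite_difference(self, D: np.ndarray) -> np.ndarray:
        h = self.fd_step
        if h is None:
            nD = np.linalg.norm(D)
            h = 1e-3 * np.linalg.norm(self._R0) / nD if nD > 0 else 1.0
        Ws = []
        for sgn in (+1.0, -1.0):
            sub = PopulationManifold(n_components=self.K_).fit(self._R0 + sgn * h * D)
            Omega, _ = orthogonal_procrustes(sub.W_, self.W_)
            Ws.append(sub.W_ @ Omega)
        return (Ws[0] - Ws[1]) / (2.0 * h)

    # ------------------------------------------------------------------
    def evaluate_trajectory(self, dz: dict) -> np.ndarray:
        """Latent trajectories (K, T) at kinematic deviations ``dz``."""
        check_is_fitted(self, "P_")
        P = self.P_.copy()
        for name, value in dz.items():
            if name not in self.dPdz_:
                raise KeyError(f"no derivative computed for parameter {name!r}")
            P = P + float(value) * self.dPdz_[name]
        return P

    def cross_validation_curve(self, n_folds: int = 10, seed: int = 0) -> np.ndarray:
        """Held-out-unit reconstruction error as a function of K.

        Units are split into ~N/10-sized folds; held-out unit rates are
        regressed onto the latent trajectories of the remaining units and
        the relative reconstruction error averaged over folds.
        """
        check_is_fitted(self, "W_")
        R0 = self._R0
        N = R0.shape[0]
        rng = np.random.default_rng(seed)
        order = rng.permutation(N)
        folds = np.array_split(order, min(n_folds, N))
        kmax = min(N - max(len(f) for f in folds), self.singular_values_.size)
        errs = np.zeros(kmax)
        for fold in folds:
            keep = np.setdiff1d(order, fold)
            sub = PopulationManifold(n_components=kmax).fit(R0[keep])
            for k in range(1, kmax + 1):
                Pk = sub.P_[:k]
                coef, _, _, _ = np.linalg.lstsq(Pk.T, R0[fold].T, rcond=None)
                recon = (Pk.T @ coef).T
                errs[k - 1] += ((R0[fold] - recon) ** 2).sum()
        return errs / (R0**2).sum() / 1.0


def fit_base_manifold(
    R0: np.ndarray, variance_threshold: float = 0.85, **kwargs
) -> PopulationManifold:
    """Convenience wrapper over :class:`PopulationManifold`."""
    return PopulationManifold(variance_threshold=variance_threshold, **kwargs).fit(R0)


def procrustes_align(P: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Orthogonally rotate latent trajectories (K, T) onto a reference."""
    Omega, _ = orthogonal_procrustes(P.T, reference.T)
    return (P.T @ Omega).T


# ----------------------------------------------------------------------
# geometry and dynamics statistics
# ----------------------------------------------------------------------

def smooth_trajectory(P: np.ndarray, sd_bins: float) -> np.ndarray:
    """Gaussian-smooth latent trajectories along time (rows = dimensions).

    Used before phase-based statistics: the rotation phase about the
    reference point is hypersensitive to high-frequency noise when the
    trajectory passes close to it.
    """
    if sd_bins <= 0:
        return P
    half = int(np.ceil(4 * sd_bins))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sd_bins) ** 2)
    k /= k.sum()
    pad = np.pad(P, [(0, 0), (half, half)], mode="edge")
    return np.stack([np.convolve(row, k, mode="valid") for row in pad])


def manifold_size(xy: np.ndarray) -> float:
    """Enclosed area of a closed 2-D trajectory.

    Sum of signed triangle areas spanned by consecutive point pairs and the
    origin (shoelace formula over the closed polyline); absolute value.
    """
    xy = np.asarray(xy, float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) trajectory")
    x, y = xy[:, 0], xy[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    return float(abs(0.5 * np.sum(x * y2 - x2 * y)))


def rotation_phase(xy: np.ndarray) -> np.ndarray:
    """Unwrapped rotation phase (deg) about the reference (max(x)/2, 0).

    The trajectory is first oriented so its dominant excursion points along
    +x (PCA latent signs are arbitrary; the reference-point construction
    assumes the loop sweeps through positive x).  The phase is
    quadrant-aware and continuous, shifted to start near -180 deg at the
    first sample (trajectories begin on the far side of the reference
    point at trial start, t = -250 ms).
    """
    xy = np.asarray(xy, float)
    x = xy[:, 0]
    if abs(x.min()) > abs(x.max()):
        x = -x
    x0 = x.max() / 2.0
    theta = np.degrees(np.unwrap(np.arctan2(xy[:, 1], x - x0)))
    if theta[0] > 0:
        theta = theta - 360.0
    return theta


def rotation_speed(
    xy: np.ndarray, t_ms: np.ndarray
) -> tuple[float, float]:
    """Average rotation speed 270 deg / T_3/4 of a 2-D trajectory.

    T_3/4 is the time from the trajectory start (phase ~ -180 deg) to the
    first crossing of +90 deg (three quarter turns), interpolated between
    samples.  Returns (speed deg/ms, T_3/4 ms); (nan, nan) when the
    rotation never completes 3/4 of a cycle.
    """
    xy = np.asarray(xy, float)
    t_ms = np.asarray(t_ms, float)
    theta = rotation_phase(xy)
    if theta[-1] < theta[0]:            # clockwise: mirror to CCW convention
        theta = -theta - 360.0
    target = 90.0
    above = np.flatnonzero(theta >= target)
    if above.size == 0 or above[0] == 0:
        return float("nan"), float("nan")
    i = above[0]
    frac = (target - theta[i - 1]) / (theta[i] - theta[i - 1])
    t_cross = t_ms[i - 1] + frac * (t_ms[i] - t_ms[i - 1])
    t34 = float(t_cross - t_ms[0])
    return 270.0 / t34, t34


def slope_angle(
    sizes: np.ndarray, speeds: np.ndarray, control_sds: tuple[float, float]
) -> float:
    """Angle (deg) of the size-speed relationship in normalized coordinates.

    Both coordinates are divided by the control-case standard deviations
    before a least-squares line is fitted; the angle is arctan(slope),
    in (-90, 90].  Constant speeds give 0 deg, constant sizes 90 deg.
    """
    sizes = np.asarray(sizes, float)
    speeds = np.asarray(speeds, float)
    if sizes.size < 2:
        raise ValueError("need >= 2 (size, speed) pairs")
    sd_x, sd_y = control_sds
    if sd_x <= 0 or sd_y <= 0:
        raise ValueError("control SDs must be positive")
    x = sizes / sd_x
    y = speeds / sd_y
    vx = x - x.mean()
    vy = y - y.mean()
    sxx = float(vx @ vx)
    if sxx < 1e-12 * max(float(vy @ vy), 1.0):
        return 90.0
    slope = float(vx @ vy) / sxx
    return float(np.degrees(np.arctan(slope)))


def align_cca(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Canonical correlations between two latent trajectory sets.

    ``A`` (K_A, T) and ``B`` (K_B, T) share the time axis; returns the
    canonical correlations in descending order.  Invariant to invertible
    linear maps of either set, so a rotated copy of a manifold correlates
    perfectly with the original.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("trajectory sets must share the time axis")
    X = A.T - A.T.mean(axis=0)
    Y = B.T - B.T.mean(axis=0)
    for M, name in ((X, "A"), (Y, "B")):
        if np.any(M.std(axis=0) < 1e-12):
            raise ValueError(f"constant channel in trajectory set {name}")
    Qx, _ = qr(X, mode="economic")
    Qy, _ = qr(Y, mode="economic")
    rho = svdvals(Qx.T @ Qy)[: min(A.shape[0], B.shape[0])]
    return np.clip(rho, 0.0, 1.0)


def encoding_dimensionality(D: np.ndarray, target: float) -> int:
    """Smallest dimensionality explaining ``target`` of the variance of a
    kinematics-derivative matrix (N units x T)."""
    D = np.asarray(D, float)
    s = np.linalg.svd(D, compute_uv=False)
    frac = np.cumsum(s**2) / np.sum(s**2)
    return int(np.searchsorted(frac, target - 1e-12) + 1)


def eigenvalue_stability(
    R0: np.ndarray, D: np.ndarray, deltas: np.ndarray, n_eigs: int | None = None
) -> dict:
    """Leading eigenvalues of the perturbed second-moment matrix across a
    dz grid, with the first-order prediction and the max relative change."""
    R0 = np.asarray(R0, float)
    D = np.asarray(D, float)
    T = R0.shape[1]
    C0 = R0 @ R0.T / T
    lam0, V = np.linalg.eigh(C0)
    lam0, V = lam0[::-1], V[:, ::-1]
    k = n_eigs or min(10, lam0.size)
    dC = (D @ R0.T + R0 @ D.T) / T
    first_order_rate = np.array([V[:, i] @ dC @ V[:, i] for i in range(k)])
    spectra = []
    for dz in np.asarray(deltas, float):
        Rz = R0 + dz * D
        lam = np.linalg.eigvalsh(Rz @ Rz.T / T)[::-1][:k]
        spectra.append(lam)
    spectra = np.array(spectra)
    # relative changes are meaningful only for non-negligible eigenvalues
    sig = lam0[:k] > 1e-9 * max(lam0[0], 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(spectra[:, sig] - lam0[:k][sig]) / lam0[:k][sig]
    return dict(
        deltas=np.asarray(deltas, float),
        eigenvalues=spectra,
        base=lam0[:k],
        first_order=np.add.outer(np.asarray(deltas, float), np.zeros(k))
        * first_order_rate
        + lam0[:k],
        max_relative_change=float(np.nanmax(rel)) if spectra.size else 0.0,
    )
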