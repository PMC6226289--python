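"""Thin-film active chiral fluid model: forward solver and parameter fitting.

The cortex is treated as a thin film of an active chiral viscous fluid.
With active tension T = alpha * I and active torque density tau = beta * I
proportional to the myosin fluorescence intensity I(x), the steady-state
force and torque balances along the AP axis reduce (after dividing by the
friction coefficient gamma) to two decoupled boundary-value problems

    lambda^2      * vx'' - vx = alpha_eff * dI/dx          (tension)
    lambda^2 / 2  * vy'' - vy = beta_eff  * dI/dx          (torque)

where ``lambda = sqrt(eta / gamma)`` is the hydrodynamic length (the
range over which stresses propagate), ``alpha_eff = alpha / gamma`` and
``beta_eff = beta / gamma``.  Viscosity and friction are not separately
identifiable from flow profiles; only lambda, alpha_eff and beta_eff are.
The chirality index ``c = tau / T = beta_eff / alpha_eff`` quantifies
rotation relative to contraction.  The factor 1/2 in the torque equation
makes the chiral decay length lambda / sqrt(2).

Both equations are linear in (alpha_eff, beta_eff), which the fit
exploits: for a fixed lambda the coefficients follow from linear least
squares, and lambda alone is found by a bounded 1-D search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg, optimize, stats

from .geometry import BinnedProfile

__all__ = [
    "ActiveGelParams",
    "CortexFit",
    "solve_flow_profile",
    "fit_cortex",
    "fit_significance",
]


@dataclass
class ActiveGelParams:
    """Fitted material parameters of the cortex.

    lambda_um is the hydrodynamic length; alpha_eff/beta_eff map the
    (unit-mean normalized) intensity to tension/torque forcing, in
    um/min * um per intensity unit; c = beta_eff / alpha_eff.
    """

    lambda_um: float
    alpha_eff: float
    beta_eff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lambda_um <= 0:
            raise ValueError("lambda must be positive")

    @property
    def c(self) -> Optional[float]:
        if self.beta_eff is None or self.alpha_eff == 0:
            return None
        return self.beta_eff / self.alpha_eff


@dataclass
class CortexFit:
    """Result of a least-squares fit of the model to a binned profile."""

    params: ActiveGelParams
    se_lambda: float
    se_alpha: float
    se_beta: Optional[float]
    se_c: Optional[float]
    ssr: float
    n_data: int
    chirality_included: bool
    boundary_fit: bool
    model_vx: np.ndarray
    model_vy: Optional[np.ndarray]
    bin_centers: np.ndarray

    @property
    def lambda_um(self) -> float:
        return self.params.lambda_um

    @property
    def c(self) -> Optional[float]:
        return self.params.c

    def to_dict(self) -> dict:
        return {
            "lambda_um": self.params.lambda_um,
            "lambda_se": self.se_lambda,
            "alpha_eff": self.params.alpha_eff,
            "beta_eff": self.params.beta_eff,
            "c": self.c,
            "c_se": self.se_c,
            "ssr": self.ssr,
            "n_data": self.n_data,
            "chirality_included": self.chirality_included,
            "boundary_flag": self.boundary_fit,
        }


def _solve_helmholtz(
    coeff: float, forcing: np.ndarray, h: float, bc: tuple[float, float]
) -> np.ndarray:
    """Solve coeff * v'' - v = forcing with Dirichlet BCs on a uniform grid.

    Second-order central differences; tridiagonal banded solve.
    """
    n = forcing.size
    if n < 3:
        raise ValueError("grid too small")
    m = n - 2
    main = np.full(m, -2.0 * coeff / h**2 - 1.0)
    off = np.full(m - 1, coeff / h**2)
    rhs = forcing[1:-1].copy()
    rhs[0] -= coeff / h**2 * bc[0]
    rhs[-1] -= coeff / h**2 * bc[1]
    ab = np.zeros((3, m))
    ab[0, 1:] = off
    ab[1] = main
    ab[2, :-1] = off
    interior = linalg.solve_banded((1, 1), ab, rhs)
    return np.concatenate([[bc[0]], interior, [bc[1]]])


def _gradient(y: np.ndarray, h: float) -> np.ndarray:
    """Central differences in the interior, one-sided at the ends."""
    return np.gradient(y, h)


def solve_flow_profile(
    I: np.ndarray,
    x: np.ndarray,
    lambda_um: float,
    alpha_eff: float,
    beta_eff: float,
    bc_vx: tuple[float, float] = (0.0, 0.0),
    bc_vy: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the two model boundary-value problems on a uniform grid.

    Returns (vx, vy) on the grid ``x``.  The intensity gradient is taken
    by central differences.
    """
    x = np.asarray(x, dtype=float)
    I = np.asarray(I, dtype=float)
    if x.size != I.size:
        raise ValueError("x and I must have equal length")
    if x.size < 10:
        raise ValueError("grid must have at least 10 points")
    h = x[1] - x[0]
    if not np.allclose(np.diff(x), h, rtol=1e-8, atol=1e-10):
        raise ValueError("grid must be uniform")
    if lambda_um <= 0:
        raise ValueError("lambda must be positive")
    dIdx = _gradient(I, h)
    vx = _solve_helmholtz(lambda_um**2, alpha_eff * dIdx, h, bc_vx)
    vy = _solve_helmholtz(lambda_um**2 / 2.0, beta_eff * dIdx, h, bc_vy)
    return vx, vy


def _model_on_bins(
    lam: float,
    I_fine: np.ndarray,
    x_fine: np.ndarray,
    bins_x: np.ndarray,
    bc_vx: tuple[float, float],
    bc_vy: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Basis solutions evaluated at bin centres.

    By linearity, vx(lam, alpha) = hx + alpha * px where hx solves the
    homogeneous problem with the data boundary conditions and px the
    forced problem with zero BCs; likewise for vy.
    """
    h = x_fine[1] - x_fine[0]
    dIdx = _gradient(I_fine, h)
    zeros = np.zeros_like(I_fine)
    hx = _solve_helmholtz(lam**2, zeros, h, bc_vx)
    px = _solve_helmholtz(lam**2, dIdx, h, (0.0, 0.0))
    hy = _solve_helmholtz(lam**2 / 2.0, zeros, h, bc_vy)
    py = _solve_helmholtz(lam**2 / 2.0, dIdx, h, (0.0, 0.0))
    interp = lambda v: np.interp(bins_x, x_fine, v)
    return interp(hx), interp(px), interp(hy), interp(py)


def _linear_coefficient(
    basis: np.ndarray, target: np.ndarray, weights: np.ndarray
) -> float:
    denom = float(np.sum(weights * basis**2))
    if denom == 0:
        return 0.0
    return float(np.sum(weights * basis * target) / denom)


def fit_cortex(
    profile: BinnedProfile,
    include_chirality: bool = True,
    lambda_bounds: tuple[float, float] = (1.0, 200.0),
    n_grid: int = 200,
    weight_by_sem: bool = False,
) -> CortexFit:
    """Least-squares fit of the active-gel model to a binned profile.

    The intensity is normalized to unit mean (fluorescence units are
    arbitrary; c and lambda are invariant to this normalization), then
    linearly interpolated onto an ``n_grid``-point uniform grid spanning
    the non-missing bin centres.  Boundary conditions are the measured
    velocities at the two extreme non-missing bins.  The total SSR sums
    squared vx residuals and, when ``include_chirality``, vy residuals.
    Standard errors come from the finite-difference Hessian of the SSR
    at the optimum via the usual nonlinear-least-squares covariance
    ``2 * s^2 * H^{-1}`` with ``s^2 = SSR / (n - p)``.
    """
    ok = ~profile.missing & np.isfinite(profile.I) & np.isfinite(profile.vx)
    if include_chirality:
        ok &= np.isfinite(profile.vy)
    if int(np.sum(ok)) < 6:
        raise ValueError("need at least 6 non-missing bins to fit")
    xb = profile.bin_centers[ok]
    I_obs = profile.I[ok]
    if np.any(I_obs <= 0):
        raise ValueError("intensity must be positive")
    vx_obs = profile.vx[ok]
    vy_obs = profile.vy[ok] if include_chirality else np.zeros_like(vx_obs)

    I_norm = I_obs / np.mean(I_obs)
    x_fine = np.linspace(xb[0], xb[-1], n_grid)
    I_fine = np.interp(x_fine, xb, I_norm)
    bc_vx = (float(vx_obs[0]), float(vx_obs[-1]))
    bc_vy = (float(vy_obs[0]), float(vy_obs[-1]))

    if weight_by_sem:
        wx = 1.0 / np.clip(profile.sem_vx[ok], 1e-12, None) ** 2
        wy = 1.0 / np.clip(profile.sem_vy[ok], 1e-12, None) ** 2
    else:
        wx = np.ones_like(vx_obs)
        wy = np.ones_like(vx_obs)

    def coeffs_and_ssr(lam: float) -> tuple[float, float, float]:
        hx, px, hy, py = _model_on_bins(lam, I_fine, x_fine, xb, bc_vx, bc_vy)
        alpha = _linear_coefficient(px, vx_obs - hx, wx)
        rx = vx_obs - hx - alpha * px
        ssr = float(np.sum(wx * rx**2))
        beta = 0.0
        if include_chirality:
            beta = _linear_coefficient(py, vy_obs - hy, wy)
            ry = vy_obs - hy - beta * py
            ssr += float(np.sum(wy * ry**2))
        return alpha, beta, ssr

    # Coarse log-spaced scan then local bounded refinement: the SSR can
    # have local minima in lambda, so a multi-start-style global scan
    # precedes the scalar minimization.
    lo, hi = lambda_bounds
    scan = np.geomspace(lo, hi, 60)
    scan_ssr = np.array([coeffs_and_ssr(l)[2] for l in scan])
    i_best = int(np.argmin(scan_ssr))
    bracket_lo = scan[max(i_best - 1, 0)]
    bracket_hi = scan[min(i_best + 1, scan.size - 1)]
    res = optimize.minimize_scalar(
        lambda l: coeffs_and_ssr(l)[2],
        bounds=(bracket_lo, bracket_hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam_hat = float(res.x)
    alpha_hat, beta_hat, ssr = coeffs_and_ssr(lam_hat)
    boundary = bool(
        np.isclose(lam_hat, lo, rtol=1e-3) or np.isclose(lam_hat, hi, rtol=1e-3)
    )

    def ssr_at(theta: np.ndarray) -> float:
        lam, alpha = theta[0], theta[1]
        beta = theta[2] if include_chirality else 0.0
        hx, px, hy, py = _model_on_bins(lam, I_fine, x_fine, xb, bc_vx, bc_vy)
        rx = vx_obs - hx - alpha * px
        s = float(np.sum(wx * rx**2))
        if include_chirality:
            ry = vy_obs - hy - beta * py
            s += float(np.sum(wy * ry**2))
        return s

    theta = np.array(
        [lam_hat, alpha_hat, beta_hat] if include_chirality else [lam_hat, alpha_hat]
    )
    n_data = vx_obs.size * (2 if include_chirality else 1)
    p = theta.size
    cov, ses = _hessian_covariance(ssr_at, theta, ssr, n_data, p)
    se_lambda, se_alpha = ses[0], ses[1]
    se_beta = ses[2] if include_chirality else None

    c = None
    se_c = None
    if include_chirality:
        if abs(alpha_hat) > 1e-12:
            c = beta_hat / alpha_hat
            grad = np.array([-beta_hat / alpha_hat**2, 1.0 / alpha_hat])
            block = cov[1:3, 1:3]
            var_c = float(grad @ block @ grad)
            se_c = float(np.sqrt(max(var_c, 0.0)))

    hx, px, hy, py = _model_on_bins(lam_hat, I_fine, x_fine, xb, bc_vx, bc_vy)
    model_vx = hx + alpha_hat * px
    model_vy = hy + beta_hat * py if include_chirality else None

    params = ActiveGelParams(
        lambda_um=lam_hat,
        alpha_eff=alpha_hat,
        beta_eff=beta_hat if include_chirality else None,
    )
    return CortexFit(
        params=params,
        se_lambda=se_lambda,
        se_alpha=se_alpha,
        se_beta=se_beta,
        se_c=se_c,
        ssr=ssr,
        n_data=n_data,
        chirality_included=include_chirality,
        boundary_fit=boundary,
        model_vx=model_vx,
        model_vy=model_vy,
        bin_centers=xb,
    )


def _hessian_covariance(
    fun, theta: np.ndarray, ssr: float, n_data: int, p: int
) -> tuple[np.ndarray, np.ndarray]:
    """Central finite-difference Hessian of the SSR -> parameter covariance."""
    k = theta.size
    H = np.zeros((k, k))
    steps = 1e-4 * np.maximum(np.abs(theta), 1e-3)
    f0 = ssr
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        H[i, i] = (fun(theta + ei) - 2 * f0 + fun(theta - ei)) / steps[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej)
                - fun(theta + ei - ej)
                - fun(theta - ei + ej)
                + fun(theta - ei - ej)
            ) / (4 * steps[i] * steps[j])
    s2 = ssr / max(n_data - p, 1)
    try:
        cov = 2.0 * s2 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    # pad covariance to 3x3 layout for the c-propagation when chirality off
    if k == 2:
        full = np.full((3, 3), np.nan)
        full[:2, :2] = cov
        cov = full
    return cov, ses


def fit_significance(
    fit_a: CortexFit,
    fit_b: CortexFit,
    quantity: str = "lambda",
    confidence: float = 0.99,
) -> tuple[float, bool]:
    """Two-sided z-test on a fitted quantity using the Hessian-based SEs.

    p = 2 * (1 - Phi(|theta_a - theta_b| / sqrt(SE_a^2 + SE_b^2))),
    significant iff p < 1 - confidence.
    """
    if quantity == "lambda":
        ta, sa = fit_a.params.lambda_um, fit_a.se_lambda
        tb, sb = fit_b.params.lambda_um, fit_b.se_lambda
    elif quantity == "c":
        if fit_a.c is None or fit_b.c is None or fit_a.se_c is None or fit_b.se_c is None:
            raise ValueError("chirality index undefined for one of the fits")
        ta, sa = fit_a.c, fit_a.se_c
        tb, sb = fit_b.c, fit_b.se_c
    else:
        raise ValueError("quantity must be 'lambda' or 'c'")
    if not (np.isfinite(sa) and np.isfinite(sb)):
        raise ValueError("fit standard errors are not finite")
    denom = np.sqrt(sa**2 + sb**2)
    if denom == 0:
        p = 0.0 if ta != tb else 1.0
    else:
        z = abs(ta - tb) / denom
        p = float(2.0 * stats.norm.sf(z))
    return p, p < (1.0 - confidence)
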