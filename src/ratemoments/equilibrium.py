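"""Steady state of the closure system and the quasi-steady-state baseline.

Under constant drive the closure ODEs settle to a fixed point satisfying

    mu_j      = mu_tilde_j + sum_k g_jk E1(k)
    sigma_j^2 = sigma_tilde_j^2 / (2 tau_j) + sigma_j sum_k g_jk M_F(j,k)
    Cov_jk (tau_j + tau_k)/2
              = c_jk sigma_tilde_j sigma_tilde_k / 2
                + (sigma_j tau_j / 2) sum_l g_kl M_F(j,l)
                + (sigma_k tau_k / 2) sum_l g_jl M_F(k,l)

The (mu, sigma) subsystem is implicit and is solved by damped fixed-point
iteration (with a root-finder fallback); the covariance relation is then
explicit.  The quasi-steady-state (QSS) baseline evaluates this fixed
point at each instant's drive values, ignoring relaxation dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .expectations import sigmoid_moments
from .moments import firing_statistics
from .network import NetworkSpec, eval_input
from .trajectory import StatTrajectory, pair_indices

__all__ = ["SteadyState", "solve_steady_state", "qss_trajectory", "steady_state_residual"]


@dataclass
class SteadyState:
    """Converged (or best-effort) fixed point of the closure system."""

    mu: np.ndarray
    sigma: np.ndarray
    cov: np.ndarray
    converged: bool
    residual_norm: float
    iterations: int

    @property
    def n_cells(self) -> int:
        return self.mu.shape[0]


def _closure_maps(spec: NetworkSpec, mu, sigma):
    """(E1 vector, M matrix) with M[j,k] = c_jk * m1(k) (c_jj = 1)."""
    e1v, _, m1v = sigmoid_moments(spec.x_rev, spec.x_sp, mu, sigma)
    return e1v, spec.corr * m1v[None, :]


def steady_state_residual(
    spec: NetworkSpec,
    mu: np.ndarray,
    sigma: np.ndarray,
    mu_tilde: np.ndarray,
    sigma_tilde: np.ndarray,
) -> np.ndarray:
    """Stacked residual of the mean and variance fixed-point relations."""
    e1v, mmat = _closure_maps(spec, mu, sigma)
    g = spec.coupling
    r_mu = mu - mu_tilde - g @ e1v
    a = sigma_tilde**2 / (2.0 * spec.tau)
    b = (g * mmat).sum(axis=1)
    r_sigma = sigma**2 - a - sigma * b
    return np.concatenate([r_mu, r_sigma])


def _covariance_from(spec: NetworkSpec, mu, sigma, sigma_tilde) -> np.ndarray:
    _, mmat = _closure_maps(spec, mu, sigma)
    g = spec.coupling
    tau = spec.tau
    # P[j,k] = sigma_j tau_j sum_l g_kl M[j,l]
    p = (sigma * tau)[:, None] * (mmat @ g.T)
    cov = (spec.corr * np.outer(sigma_tilde, sigma_tilde) + p + p.T) / (
        tau[:, None] + tau[None, :]
    )
    cov = 0.5 * (cov + cov.T)
    np.fill_diagonal(cov, sigma**2)
    return cov


def solve_steady_state(
    spec: NetworkSpec,
    mu_tilde=None,
    sigma_tilde=None,
    tol: float = 1e-12,
    max_iter: int = 500,
    damping: float = 0.5,
    init: tuple | None = None,
) -> SteadyState:
    """Solve the closure fixed point for the given (constant) drive values.

    The damped iteration updates mu from the mean relation and sigma from
    the positive root of its scalar quadratic sigma^2 - sigma*B_j - A_j = 0
    (A_j > 0 guarantees a positive root whenever sigma_tilde_j > 0).  If the
    iteration stalls, a Powell-hybrid root-finder is tried on the stacked
    residual.  Non-convergence is reported, not raised.
    """
    mu_tilde = np.asarray(spec.mu_bg if mu_tilde is None else mu_tilde, dtype=float)
    sigma_tilde = np.asarray(spec.sigma_bg if sigma_tilde is None else sigma_tilde, dtype=float)
    if np.any(sigma_tilde <= 0):
        raise ValueError("steady-state solve requires strictly positive noise amplitudes")
    g = spec.coupling
    a = sigma_tilde**2 / (2.0 * spec.tau)

    if init is None:
        mu = mu_tilde.copy()
        sigma = np.sqrt(a)
    else:
        mu = np.asarray(init[0], dtype=float).copy()
        sigma = np.asarray(init[1], dtype=float).copy()

    converged = False
    iterations = 0
    resid = np.inf
    for iterations in range(1, max_iter + 1):
        e1v, mmat = _closure_maps(spec, mu, sigma)
        mu_new = mu_tilde + g @ e1v
        b = (g * mmat).sum(axis=1)
        sigma_new = 0.5 * (b + np.sqrt(b * b + 4.0 * a))
        mu = (1.0 - damping) * mu + damping * mu_new
        sigma = (1.0 - damping) * sigma + damping * sigma_new
        resid = float(
            np.max(np.abs(steady_state_residual(spec, mu, sigma, mu_tilde, sigma_tilde)))
        )
        if resid <= tol:
            converged = True
            break

    if not converged:
        def stacked(z):
            return steady_state_residual(
                spec, z[: spec.n_cells], z[spec.n_cells :], mu_tilde, sigma_tilde
            )

        sol = optimize.root(stacked, np.concatenate([mu, sigma]), method="hybr")
        cand_mu = sol.x[: spec.n_cells]
        cand_sigma = sol.x[spec.n_cells :]
        cand_resid = float(np.max(np.abs(stacked(sol.x))))
        if sol.success and cand_resid <= tol and np.all(cand_sigma > 0):
            mu, sigma, resid, converged = cand_mu, cand_sigma, cand_resid, True
        elif cand_resid < resid and np.all(cand_sigma > 0):
            mu, sigma, resid = cand_mu, cand_sigma, cand_resid

    cov = _covariance_from(spec, mu, sigma, sigma_tilde)
    return SteadyState(
        mu=mu,
        sigma=sigma,
        cov=cov,
        converged=converged,
        residual_norm=resid,
        iterations=iterations,
    )


def qss_trajectory(
    spec: NetworkSpec,
    times,
    tol: float = 1e-12,
    max_iter: int = 500,
    firing_corr_mode: str = "dynamic",
) -> StatTrajectory:
    """Quasi-steady-state baseline: the fixed point at each instant's drive.

    Each solve is warm-started from the previous time's solution.  Firing
    statistics are derived by the same change of variables as the closure.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or not np.all(np.isfinite(times)):
        raise ValueError("times must be a finite 1-D grid")
    n = spec.n_cells
    jj, kk = pair_indices(n)
    nt = times.size
    mean = np.empty((nt, n))
    var = np.empty((nt, n))
    cov = np.empty((nt, jj.size))
    warm = None
    for i, t in enumerate(times):
        mu_bg, sig_bg = eval_input(spec, float(t))
        ss = solve_steady_state(
            spec,
            mu_tilde=mu_bg,
            sigma_tilde=sig_bg,
            tol=tol,
            max_iter=max_iter,
            init=warm,
        )
        if not ss.converged:
            raise RuntimeError(
                f"QSS solve failed at t={t:.6g} (residual {ss.residual_norm:.3e})"
            )
        warm = (ss.mu, ss.sigma)
        mean[i] = ss.mu
        var[i] = ss.sigma**2
        cov[i] = ss.cov[jj, kk]
    nu, var_nu, cov_nu = firing_statistics(spec, mean, var, cov, mode=firing_corr_mode)
    return StatTrajectory(
        times=times,
        mean_activity=mean,
        var_activity=var,
        cov_activity=cov,
        mean_firing=nu,
        var_firing=var_nu,
        cov_firing=cov_nu,
        provenance="qss",
    )
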