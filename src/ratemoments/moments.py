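"""Closure ODE system for the network's first and second moments.

The state consists of the per-cell means mu_j and the symmetric matrix of
raw second moments E[x_j x_k] (N + N(N+1)/2 free variables).  Closing the
moment hierarchy under a pairwise-Gaussian assumption for the activity
yields a coupled nonlinear ODE system whose right-hand side involves the
Gaussian sigmoid expectations E1 and the mixed moments M_F.

Per-cell mean channel:

    d(mu_j)/dt = (-mu_j + mu_tilde_j(t) + sum_k g_jk E1(k)) / tau_j

Second-moment channel (one formula covers diagonal and off-diagonal; the
j = k instance reproduces the dedicated variance equation):

    tau_j tau_k dE_jk/dt = c_jk sigma_tilde_j(t) sigma_tilde_k(t)
        + tau_k [ -E_jk + mu_tilde_j(t) mu_k
                  + sum_l g_jl (mu_k E1(l) + sigma_k M_F(k,l)) ]
        + tau_j [ -E_jk + mu_tilde_k(t) mu_j
                  + sum_l g_kl (mu_j E1(l) + sigma_j M_F(j,l)) ]

where M_F(j,k) = c_jk * E[F_k Y] uses the static input noise correlation,
with c_jj = 1 (univariate replacement on the diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .expectations import QuadratureRule, bivariate_rate_expectation, sigmoid_moments
from .network import NetworkSpec, eval_input
from .trajectory import StatTrajectory, pair_indices

__all__ = [
    "MomentState",
    "ClosureConfig",
    "ClosureBreakdownError",
    "SolverError",
    "closure_rhs",
    "integrate_closure",
    "activity_to_firing",
    "firing_statistics",
]

#: variance more negative than this indicates closure failure, not round-off
VARIANCE_FLOOR = -1e-8


class ClosureBreakdownError(RuntimeError):
    """Raised when derived moments leave the admissible region."""


class SolverError(RuntimeError):
    """Raised when the ODE integrator fails to reach the end of the grid."""


@dataclass(frozen=True)
class ClosureConfig:
    """Numerical settings for the closure integration.

    ``firing_corr_mode``: correlation used in the output change of variables
    for the firing covariance — ``"dynamic"`` uses the evolving activity
    correlation Cov_jk/(sigma_j sigma_k); ``"static_input"`` uses the fixed
    input noise correlation c_jk (ablation mode).
    """

    quad_order: int = 40
    rtol: float = 1e-8
    atol: float = 1e-10
    init_mode: str = "steady_state_at_t0"
    firing_corr_mode: str = "dynamic"
    method: str = "RK45"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be positive")
        if self.quad_order < 1:
            raise ValueError("quadrature order must be >= 1")
        if self.init_mode not in ("steady_state_at_t0", "user_supplied"):
            raise ValueError("init_mode must be 'steady_state_at_t0' or 'user_supplied'")
        if self.firing_corr_mode not in ("dynamic", "static_input"):
            raise ValueError("firing_corr_mode must be 'dynamic' or 'static_input'")


@dataclass
class MomentState:
    """Means and raw second moments of the activity at one instant."""

    mu: np.ndarray
    second_moments: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.second_moments = np.asarray(self.second_moments, dtype=float)
        n = self.mu.shape[0]
        if self.mu.ndim != 1:
            raise ValueError("mu must be 1-D")
        if self.second_moments.shape != (n, n):
            raise ValueError("second_moments must be square of matching size")
        if not np.allclose(self.second_moments, self.second_moments.T, atol=1e-10, rtol=0.0):
            raise ValueError("second_moments must be symmetric")

    @property
    def n_cells(self) -> int:
        return self.mu.shape[0]

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.second_moments) - self.mu**2

    @property
    def cov(self) -> np.ndarray:
        return self.second_moments - np.outer(self.mu, self.mu)

    @property
    def dim(self) -> int:
        """Number of free variables: N + N(N+1)/2."""
        n = self.n_cells
        return n + n * (n + 1) // 2

    def flatten(self) -> np.ndarray:
        iu = np.triu_indices(self.n_cells)
        return np.concatenate([self.mu, self.second_moments[iu]])

    @classmethod
    def from_flat(cls, n_cells: int, vec: np.ndarray) -> "MomentState":
        vec = np.asarray(vec, dtype=float)
        mu = vec[:n_cells]
        e = np.zeros((n_cells, n_cells))
        iu = np.triu_indices(n_cells)
        e[iu] = vec[n_cells:]
        e.T[iu] = vec[n_cells:]
        return cls(mu=mu, second_moments=e)

    @classmethod
    def from_stats(cls, mu, cov) -> "MomentState":
        mu = np.asarray(mu, dtype=float)
        cov = np.asarray(cov, dtype=float)
        return cls(mu=mu, second_moments=cov + np.outer(mu, mu))


def _derived_sigma(mu: np.ndarray, second: np.ndarray) -> np.ndarray:
    var = np.diag(second) - mu**2
    worst = var.min() if var.size else 0.0
    if worst < VARIANCE_FLOOR:
        idx = int(np.argmin(var))
        raise ClosureBreakdownError(
            f"derived variance of cell {idx} is {worst:.3e} (< {VARIANCE_FLOOR}); "
            "the Gaussian closure has left the admissible region"
        )
    return np.sqrt(np.clip(var, 0.0, None))


def _rates(mu, second, t, spec: NetworkSpec, strict: bool = True):
    """Time derivatives (dmu, dE) of the closure system.

    With ``strict=False`` negative derived variances are clipped to zero
    instead of raising — needed inside the adaptive integrator, whose
    rejected trial steps may transiently leave the admissible region.
    """
    mu_bg, sig_bg = eval_input(spec, t)
    if strict:
        sigma = _derived_sigma(mu, second)
    else:
        sigma = np.sqrt(np.clip(np.diag(second) - mu**2, 0.0, None))
    e1v, _, m1v = sigmoid_moments(spec.x_rev, spec.x_sp, mu, sigma)
    g = spec.coupling
    tau = spec.tau
    # M[j, k] = c_jk * m1(k); unit diagonal of corr realizes the univariate rule
    mmat = spec.corr * m1v[None, :]
    h = g @ e1v
    gmt = g @ mmat.T  # (j, k) -> sum_l g_jl M[k, l]
    t_term = -second + np.outer(mu_bg + h, mu) + sigma[None, :] * gmt
    dmu = (-mu + mu_bg + h) / tau
    de = (
        spec.corr * np.outer(sig_bg, sig_bg) + tau[None, :] * t_term + tau[:, None] * t_term.T
    ) / np.outer(tau, tau)
    return dmu, de


def closure_rhs(
    state: MomentState, t: float, spec: NetworkSpec, config: ClosureConfig | None = None
) -> MomentState:
    """Right-hand side of the closure ODEs as a MomentState-shaped derivative."""
    config = config or ClosureConfig()
    if not (np.all(np.isfinite(state.mu)) and np.all(np.isfinite(state.second_moments))):
        bad = np.flatnonzero(~np.isfinite(state.flatten()))
        raise ValueError(f"non-finite closure state at flat indices {bad.tolist()}")
    dmu, de = _rates(state.mu, state.second_moments, t, spec)
    return MomentState(mu=dmu, second_moments=de)


def default_initial_state(spec: NetworkSpec, t0: float, config: ClosureConfig) -> MomentState:
    """Steady state of the constant-input system frozen at the t0 drive values."""
    from .equilibrium import solve_steady_state

    mu_bg, sig_bg = eval_input(spec, t0)
    ss = solve_steady_state(spec, mu_tilde=mu_bg, sigma_tilde=sig_bg)
    if not ss.converged:
        raise SolverError(
            f"steady-state initial condition failed to converge at t0={t0} "
            f"(residual {ss.residual_norm:.3e})"
        )
    return MomentState.from_stats(ss.mu, ss.cov)


def integrate_closure(
    spec: NetworkSpec,
    times,
    config: ClosureConfig | None = None,
    init: MomentState | None = None,
) -> StatTrajectory:
    """Integrate the closure ODEs over ``times`` and emit all six statistic families.

    Default initial condition is the steady state at the t = times[0] input
    values, so transients reflect only the time-varying drive.
    """
    config = config or ClosureConfig()
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid with >= 2 points")
    if init is None:
        init = default_initial_state(spec, float(times[0]), config)
    if init.n_cells != spec.n_cells:
        raise ValueError("initial state size does not match the network")

    n = spec.n_cells

    def rhs_flat(t, y):
        mu = y[:n]
        e = np.zeros((n, n))
        iu = np.triu_indices(n)
        e[iu] = y[n:]
        e.T[iu] = y[n:]
        dmu, de = _rates(mu, e, t, spec, strict=False)
        return np.concatenate([dmu, de[iu]])

    # cap steps by the fastest drive timescale so the controller cannot
    # leap over a pulse or a sinusoid period from a quiescent baseline
    sig_scale = min(
        (s.timescale for s in spec.inputs.values()), default=np.inf
    )
    max_step = 0.5 * min(float(spec.tau.min()), sig_scale)
    sol = solve_ivp(
        rhs_flat,
        (float(times[0]), float(times[-1])),
        init.flatten(),
        method=config.method,
        t_eval=times,
        rtol=config.rtol,
        atol=config.atol,
        max_step=max_step,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else times[0]
        raise SolverError(f"closure integration failed after t={last_t:.6g}: {sol.message}")

    iu = np.triu_indices(n)
    jj, kk = pair_indices(n)
    nt = times.size
    mean = sol.y[:n].T  # (nt, n)
    var = np.empty((nt, n))
    cov = np.empty((nt, jj.size))
    for i in range(nt):
        e = np.zeros((n, n))
        e[iu] = sol.y[n:, i]
        e.T[iu] = sol.y[n:, i]
        mu = mean[i]
        v = np.diag(e) - mu**2
        if v.size and v.min() < VARIANCE_FLOOR:
            raise ClosureBreakdownError(
                f"negative derived variance {v.min():.3e} at t={times[i]:.6g}"
            )
        var[i] = np.clip(v, 0.0, None)
        c = e - np.outer(mu, mu)
        cov[i] = c[jj, kk]
    traj = StatTrajectory(
        times=times,
        mean_activity=mean,
        var_activity=var,
        cov_activity=cov,
        provenance="closure",
    )
    return activity_to_firing(traj, spec, config)


def firing_statistics(
    spec: NetworkSpec,
    mean: np.ndarray,
    var: np.ndarray,
    cov: np.ndarray,
    mode: str = "dynamic",
    rule: QuadratureRule | None = None,
):
    """Change of variables from activity moments to firing statistics.

    ``mean``/``var`` are (nt, n), ``cov`` is (nt, n_pairs).  Returns
    (mean_firing, var_firing, cov_firing).  ``mode`` selects the pair
    correlation fed to the bivariate expectation: the evolving activity
    correlation (``"dynamic"``) or the static input correlation
    (``"static_input"``).
    """
    mean = np.atleast_2d(np.asarray(mean, dtype=float))
    var = np.atleast_2d(np.asarray(var, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if np.any(var < VARIANCE_FLOOR):
        raise ValueError("activity variances must be nonnegative")
    var = np.clip(var, 0.0, None)
    sigma = np.sqrt(var)
    nt, n = mean.shape
    jj, kk = pair_indices(n)

    e1v, e2v, _ = sigmoid_moments(
        spec.x_rev[None, :], spec.x_sp[None, :], mean, sigma, rule
    )
    nu = e1v
    var_nu = np.clip(e2v - nu**2, 0.0, None)

    cov_nu = np.empty((nt, jj.size))
    for p, (j, k) in enumerate(zip(jj, kk)):
        for i in range(nt):
            sj, sk = sigma[i, j], sigma[i, k]
            cjk = cov[i, p]
            if mode == "static_input":
                rho = spec.corr[j, k]
            else:
                if sj == 0.0 or sk == 0.0:
                    if abs(cjk) > 1e-12:
                        raise ValueError(
                            f"inconsistent moments: zero variance with nonzero covariance "
                            f"for pair ({j}, {k}) at time index {i}"
                        )
                    rho = 0.0
                else:
                    rho = float(np.clip(cjk / (sj * sk), -1.0 + 1e-12, 1.0 - 1e-12))
            joint = bivariate_rate_expectation(
                spec.fi[j], spec.fi[k], mean[i, j], mean[i, k], sj, sk, rho, rule
            )
            cov_nu[i, p] = joint - nu[i, j] * nu[i, k]
    return nu, var_nu, cov_nu


def activity_to_firing(
    traj: StatTrajectory, spec: NetworkSpec, config: ClosureConfig | None = None
) -> StatTrajectory:
    """Fill in the firing statistic families of an activity trajectory."""
    config = config or ClosureConfig()
    nu, var_nu, cov_nu = firing_statistics(
        spec,
        traj.mean_activity,
        traj.var_activity,
        traj.cov_activity,
        mode=config.firing_corr_mode,
    )
    return StatTrajectory(
        times=traj.times,
        mean_activity=traj.mean_activity,
        var_activity=traj.var_activity,
        cov_activity=traj.cov_activity,
        mean_firing=nu,
        var_firing=var_nu,
        cov_firing=cov_nu,
        provenance=traj.provenance,
    )
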