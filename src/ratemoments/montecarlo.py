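"""Ground-truth Euler--Maruyama ensemble simulation with correlated noise.

Each realization follows

    x <- x + (dt/tau) * (-x + mu_tilde(t) + G F(x)) + (sqrt(dt)/tau) * sigma_tilde(t) * (L z)

with z i.i.d. standard normal and L a factor of the noise correlation matrix
(L L^T = Cr).  All six statistic families are estimated across realizations
at each requested time, together with an error-band half-width per statistic
obtained from the spread of fixed-size realization groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .network import NetworkSpec, eval_input
from .trajectory import FAMILIES, StatTrajectory, pair_indices

__all__ = ["EnsembleEstimate", "simulate_ensemble", "error_bands"]


def error_bands(per_group_means) -> float:
    """Sample standard deviation of per-group averages: the band half-width S.

    S = sqrt( (1/(n_groups - 1)) * sum_j (X(j) - Xbar)^2 ), reported as
    Xbar +/- S (one standard deviation above and below the mean).
    """
    x = np.asarray(per_group_means, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("error bands require at least 2 group means")
    return float(np.std(x, ddof=1))


@dataclass
class EnsembleEstimate:
    """Monte Carlo statistics plus per-statistic error-band half-widths."""

    trajectory: StatTrajectory
    bands: Dict[str, np.ndarray]
    n_realizations: int
    group_size: int

    def __post_init__(self) -> None:
        for fam in FAMILIES:
            if fam not in self.bands:
                raise ValueError(f"missing error band for family {fam!r}")
            if self.bands[fam].shape != self.trajectory.family(fam).shape:
                raise ValueError(f"band shape mismatch for family {fam!r}")
            if np.any(self.bands[fam] < 0):
                raise ValueError("error bands must be nonnegative")


def _psd_factor(mat: np.ndarray, name: str) -> np.ndarray:
    """Symmetric square-root factor with round-off eigenvalue clipping."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() < -1e-10:
        # one jitter attempt, then fail loudly
        vals, vecs = np.linalg.eigh(mat + 1e-10 * np.eye(mat.shape[0]))
        if vals.min() < -1e-10:
            raise np.linalg.LinAlgError(
                f"{name} is not positive semidefinite (min eigenvalue {vals.min():.3e})"
            )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _default_initial_sample(
    spec: NetworkSpec, t0: float, n_realizations: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw initial states from the Gaussian closure steady state at the t0 drive.

    Falls back to the uncoupled Gaussian steady state if the coupled solve
    does not converge.
    """
    from .equilibrium import solve_steady_state

    mu_bg, sig_bg = eval_input(spec, t0)
    if np.all(sig_bg > 0):
        ss = solve_steady_state(spec, mu_tilde=mu_bg, sigma_tilde=sig_bg)
    else:
        ss = None
    if ss is not None and ss.converged:
        mean, cov = ss.mu, ss.cov
    else:
        mean = mu_bg
        cov = spec.corr * np.outer(sig_bg, sig_bg) / (spec.tau[:, None] + spec.tau[None, :])
    # at strong coupling the pairwise closure covariance may be slightly
    # indefinite; for an initial distribution, projecting onto the PSD cone
    # is adequate (the ensemble relaxes to its own stationary law anyway)
    vals, vecs = np.linalg.eigh(cov)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n_realizations, spec.n_cells))
    return mean + z @ factor.T


def _group_stats(x: np.ndarray, nu: np.ndarray, n_groups: int, jj, kk):
    """Per-group mean/var/cov for activity and firing; ddof=1 within groups."""
    n_total, n = x.shape
    gs = n_total // n_groups
    out = {}
    for label, arr in (("activity", x), ("firing", nu)):
        g = arr.reshape(n_groups, gs, n)
        gmean = g.mean(axis=1)
        gc = g - gmean[:, None, :]
        gcov = np.matmul(gc.transpose(0, 2, 1), gc) / (gs - 1)
        out[f"mean_{label}"] = gmean
        out[f"var_{label}"] = np.diagonal(gcov, axis1=1, axis2=2).copy()
        out[f"cov_{label}"] = gcov[:, jj, kk]
    return out


def _pooled_stats(x: np.ndarray, nu: np.ndarray, jj, kk):
    n_total = x.shape[0]
    out = {}
    for label, arr in (("activity", x), ("firing", nu)):
        mean = arr.mean(axis=0)
        c = arr - mean
        cov = (c.T @ c) / (n_total - 1)
        out[f"mean_{label}"] = mean
        out[f"var_{label}"] = np.diag(cov).copy()
        out[f"cov_{label}"] = cov[jj, kk]
    return out


def simulate_ensemble(
    spec: NetworkSpec,
    times,
    n_realizations: int,
    dt: float,
    seed=None,
    group_size: int = 1000,
    burn_in: float = 0.0,
    init: Optional[np.ndarray] = None,
) -> EnsembleEstimate:
    """Simulate an Euler--Maruyama ensemble and estimate all statistic families.

    Parameters
    ----------
    times : 1-D array
        Output times; must be increasing and lie (within round-off) on the
        step grid of spacing ``dt`` anchored at ``times[0] - burn_in``.
    n_realizations : int
        Ensemble size; must be a multiple of ``group_size`` with at least
        two groups (for the error bands).
    dt : float
        Step size; required to satisfy dt <= min(tau)/10.
    init : (n_realizations, n_cells) array, optional
        Initial states; default draws from the closure steady-state
        Gaussian at the first time's drive values.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D array")
    if dt <= 0 or dt > spec.tau.min() / 10.0 + 1e-15:
        raise ValueError("dt must be positive and at most min(tau)/10")
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations")
    if n_realizations % group_size != 0 or n_realizations // group_size < 2:
        raise ValueError(
            "n_realizations must be a multiple of group_size with at least 2 groups"
        )
    if burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    n_groups = n_realizations // group_size
    rng = np.random.default_rng(seed)
    n = spec.n_cells
    jj, kk = pair_indices(n)

    t0 = float(times[0]) - burn_in
    out_steps = np.rint((times - t0) / dt).astype(int)
    if np.max(np.abs(t0 + out_steps * dt - times)) > 1e-6 * dt:
        raise ValueError("requested times must lie on the dt step grid")
    n_steps = int(out_steps[-1])

    noise_factor = _psd_factor(spec.corr, "noise correlation matrix")
    if init is None:
        x = _default_initial_sample(spec, t0, n_realizations, rng)
    else:
        x = np.array(init, dtype=float)
        if x.shape != (n_realizations, n):
            raise ValueError("init must have shape (n_realizations, n_cells)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite initial states")

    nt = times.size
    pooled = {fam: np.empty((nt, n if "cov" not in fam else jj.size)) for fam in FAMILIES}
    groups = {
        fam: np.empty((nt, n_groups, n if "cov" not in fam else jj.size)) for fam in FAMILIES
    }

    out_set = {int(s): i for i, s in enumerate(out_steps)}
    sqrt_dt = np.sqrt(dt)
    inv_tau = 1.0 / spec.tau
    g = spec.coupling

    def record(step_idx: int) -> None:
        i = out_set[step_idx]
        nu = spec.firing(x)
        ps = _pooled_stats(x, nu, jj, kk)
        gs = _group_stats(x, nu, n_groups, jj, kk)
        for fam in FAMILIES:
            pooled[fam][i] = ps[fam]
            groups[fam][i] = gs[fam]

    if 0 in out_set:
        record(0)
    for step in range(1, n_steps + 1):
        t = t0 + (step - 1) * dt
        mu_bg, sig_bg = eval_input(spec, t)
        drift = (-x + mu_bg + spec.firing(x) @ g.T) * (dt * inv_tau)
        z = rng.standard_normal((n_realizations, n))
        noise = (z @ noise_factor.T) * (sqrt_dt * sig_bg * inv_tau)
        x = x + drift + noise
        if step in out_set:
            if not np.all(np.isfinite(x)):
                bad = np.argwhere(~np.isfinite(x))[0]
                raise FloatingPointError(
                    f"non-finite activity in realization {bad[0]}, cell {bad[1]} "
                    f"at t={t0 + step * dt:.6g}"
                )
            record(step)

    bands = {
        fam: np.std(groups[fam], axis=1, ddof=1) for fam in FAMILIES
    }
    traj = StatTrajectory(
        times=times,
        mean_activity=pooled["mean_activity"],
        var_activity=pooled["var_activity"],
        cov_activity=pooled["cov_activity"],
        mean_firing=pooled["mean_firing"],
        var_firing=pooled["var_firing"],
        cov_firing=pooled["cov_firing"],
        provenance="monte_carlo",
    )
    return EnsembleEstimate(
        trajectory=traj, bands=bands, n_realizations=n_realizations, group_size=group_size
    )
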