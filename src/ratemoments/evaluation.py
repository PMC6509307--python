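"""Accuracy metrics and the coupling-strength sweep experiment.

The accuracy metric is the average absolute error: at each time, the mean of
|X_method - X_reference| over the M items of a statistic family (M = n_cells
for means and variances, M = n_cells*(n_cells-1)/2 distinct pairs for
covariances).  The grand scalar pools every (family, item, time) absolute
deviation with equal weight; per-family means are reported alongside so
either weighting convention is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .moments import ClosureConfig, integrate_closure
from .montecarlo import EnsembleEstimate, simulate_ensemble
from .equilibrium import qss_trajectory
from .network import NetworkSpec, sample_coupling, sample_network, standard_signal
from .trajectory import FAMILIES, StatTrajectory

__all__ = [
    "ErrorReport",
    "average_absolute_error",
    "compare_trajectories",
    "coupling_sweep",
    "SweepPoint",
]


def _check_aligned(method: StatTrajectory, reference: StatTrajectory) -> None:
    if method.n_cells != reference.n_cells:
        raise ValueError("trajectories have different cell counts")
    if method.times.shape != reference.times.shape or not np.allclose(
        method.times, reference.times, rtol=0.0, atol=1e-9
    ):
        raise ValueError("trajectories are on different time grids")


def average_absolute_error(
    method: StatTrajectory, reference: StatTrajectory, family: str
) -> np.ndarray:
    """Per-time mean of |method - reference| over the family's items."""
    _check_aligned(method, reference)
    diff = np.abs(method.family(family) - reference.family(family))
    return diff.mean(axis=1)


@dataclass
class ErrorReport:
    """Average-absolute-error summary of one method against a reference."""

    per_family: Dict[str, np.ndarray]
    family_means: Dict[str, float]
    grand: float
    times: np.ndarray
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fam, series in self.per_family.items():
            if np.any(np.asarray(series) < 0):
                raise ValueError(f"negative error series for family {fam!r}")


def compare_trajectories(
    method: StatTrajectory, reference: StatTrajectory, metadata: Optional[Dict] = None
) -> ErrorReport:
    """Full error report: per-family time series, per-family means, grand scalar."""
    _check_aligned(method, reference)
    per_family = {}
    pooled = []
    for fam in FAMILIES:
        diff = np.abs(method.family(fam) - reference.family(fam))
        per_family[fam] = diff.mean(axis=1)
        pooled.append(diff.ravel())
    grand = float(np.concatenate(pooled).mean())
    return ErrorReport(
        per_family=per_family,
        family_means={fam: float(series.mean()) for fam, series in per_family.items()},
        grand=grand,
        times=method.times.copy(),
        metadata=dict(metadata or {}),
    )


@dataclass
class SweepPoint:
    """Results at one coupling scale of a sweep."""

    l: float
    closure_error: ErrorReport
    qss_error: ErrorReport
    mc: EnsembleEstimate


def coupling_sweep(
    n_cells: int,
    l_values,
    input_kind: str = "pulse",
    seed: int = 0,
    times=None,
    n_realizations: int = 100_000,
    dt: float = 0.01,
    group_size: int = 1000,
    config: Optional[ClosureConfig] = None,
    rescale_base_coupling: bool = True,
) -> List[SweepPoint]:
    """Closure/QSS accuracy against Monte Carlo across coupling scales.

    One network instance (non-coupling parameters) is drawn per sweep; the
    coupling matrix is drawn once at unit scale and rescaled by ``l`` (set
    ``rescale_base_coupling=False`` to redraw it independently per scale).
    The common time-varying drive of ``input_kind`` replaces the background
    mean for all cells.
    """
    l_values = [float(l) for l in l_values]
    if any(l <= 0 for l in l_values):
        raise ValueError("coupling scales must be positive")
    config = config or ClosureConfig()
    if times is None:
        times = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)
    times = np.asarray(times, dtype=float)

    root = np.random.SeedSequence(seed)
    net_seed, coupling_seed, mc_seed = root.spawn(3)
    base = sample_network(n_cells, coupling_scale=1.0, seed=np.random.default_rng(net_seed))
    signal = standard_signal(input_kind)
    mc_children = mc_seed.spawn(len(l_values))

    results: List[SweepPoint] = []
    for i, l in enumerate(l_values):
        if rescale_base_coupling:
            coupling = base.coupling * l
        else:
            coupling = sample_coupling(
                n_cells, l, seed=np.random.default_rng(coupling_seed.spawn(1)[0])
            )
        spec = NetworkSpec(
            n_cells=n_cells,
            tau=base.tau,
            mu_bg=base.mu_bg,
            sigma_bg=base.sigma_bg,
            corr=base.corr,
            coupling=coupling,
            fi=base.fi,
        ).with_inputs(mu_bg=signal)
        closure = integrate_closure(spec, times, config=config)
        qss = qss_trajectory(spec, times, firing_corr_mode=config.firing_corr_mode)
        mc = simulate_ensemble(
            spec,
            times,
            n_realizations=n_realizations,
            dt=dt,
            seed=np.random.default_rng(mc_children[i]),
            group_size=group_size,
        )
        meta = {
            "n_cells": n_cells,
            "l": l,
            "input_kind": input_kind,
            "seed": seed,
            "n_realizations": n_realizations,
            "dt": dt,
            "t_window": [float(times[0]), float(times[-1])],
        }
        results.append(
            SweepPoint(
                l=l,
                closure_error=compare_trajectories(
                    closure, mc.trajectory, metadata={**meta, "method": "closure"}
                ),
                qss_error=compare_trajectories(
                    qss, mc.trajectory, metadata={**meta, "method": "qss"}
                ),
                mc=mc,
            )
        )
    return results
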