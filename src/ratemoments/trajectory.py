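"""Time-series container for the six statistic families.

Activity statistics (mean, variance, covariance of x) and firing statistics
(mean, variance, covariance of F(x)) on a shared time grid.  Covariances are
stored for distinct unordered pairs j < k in row-major pair order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["FAMILIES", "pair_indices", "pair_count", "StatTrajectory"]

#: canonical ordering of the six statistic families
FAMILIES = (
    "mean_activity",
    "var_activity",
    "cov_activity",
    "mean_firing",
    "var_firing",
    "cov_firing",
)

PROVENANCES = ("closure", "qss", "monte_carlo")


def pair_indices(n_cells: int):
    """Index arrays (j, k) of the distinct unordered pairs j < k, row-major."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    j, k = np.triu_indices(n_cells, k=1)
    return j, k


def pair_count(n_cells: int) -> int:
    """Number of distinct unordered pairs, n*(n-1)/2."""
    return n_cells * (n_cells - 1) // 2


@dataclass
class StatTrajectory:
    """First- and second-order statistics of activity and firing over time.

    Shapes: per-cell series are ``(n_times, n_cells)``; pair series are
    ``(n_times, n_pairs)`` with pairs ordered as :func:`pair_indices`.
    Firing statistics may be absent (``None``) until filled in by a
    change of variables.
    """

    times: np.ndarray
    mean_activity: np.ndarray
    var_activity: np.ndarray
    cov_activity: np.ndarray
    mean_firing: Optional[np.ndarray] = None
    var_firing: Optional[np.ndarray] = None
    cov_firing: Optional[np.ndarray] = None
    provenance: str = "closure"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 1:
            raise ValueError("times must be a 1-D array")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.times = times
        nt = times.size
        self.mean_activity = self._check2d("mean_activity", self.mean_activity, nt, None)
        n = self.mean_activity.shape[1]
        self.var_activity = self._check2d("var_activity", self.var_activity, nt, n)
        npair = pair_count(n)
        self.cov_activity = self._check2d("cov_activity", self.cov_activity, nt, npair)
        for name, width in (
            ("mean_firing", n),
            ("var_firing", n),
            ("cov_firing", npair),
        ):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, self._check2d(name, val, nt, width))
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")

    @staticmethod
    def _check2d(name, arr, nt, width):
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != nt:
            raise ValueError(f"{name} must have shape (n_times, ...), got {arr.shape}")
        if width is not None and arr.shape[1] != width:
            raise ValueError(f"{name} must have {width} columns, got {arr.shape[1]}")
        return arr

    @property
    def n_cells(self) -> int:
        return self.mean_activity.shape[1]

    @property
    def n_pairs(self) -> int:
        return pair_count(self.n_cells)

    @property
    def has_firing(self) -> bool:
        return self.mean_firing is not None

    def family(self, name: str) -> np.ndarray:
        if name not in FAMILIES:
            raise KeyError(f"unknown statistic family {name!r}")
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"family {name!r} has not been computed for this trajectory")
        return arr

    def with_provenance(self, provenance: str) -> "StatTrajectory":
        return replace(self, provenance=provenance)
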