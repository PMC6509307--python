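"""Network parameterization: F-I curves, time-varying drives, and random samplers.

A network is a collection of ``n_cells`` scalar activity variables, each with
a relaxation time constant, a noisy background drive (mean, noise amplitude,
instantaneous cross-cell noise correlation), all-to-all signed coupling, and a
sigmoidal activity-to-firing transfer function per cell.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "FICurveParams",
    "InputSignal",
    "NetworkSpec",
    "fi_eval",
    "sample_network",
    "build_correlation_matrix",
    "sample_coupling",
    "eval_input",
    "standard_signal",
]

#: mean of |g| for g ~ Normal(0, (l/10)^2) in the infinite-sample limit
def mean_abs_coupling(l: float) -> float:
    """Expected |g| for coupling entries drawn at scale ``l``: l/(5*sqrt(2*pi))."""
    return l / (5.0 * math.sqrt(2.0 * math.pi))


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class FICurveParams:
    """Parameters of the sigmoidal transfer F(x) = 0.5*(1 + tanh((x - x_rev)/x_sp)).

    ``x_rev`` is the half-activation point, ``x_sp`` the slope scale (> 0).
    """

    x_rev: float
    x_sp: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_rev) and np.isfinite(self.x_sp)):
            raise ValueError("F-I parameters must be finite")
        if self.x_sp <= 0:
            raise ValueError(f"x_sp must be positive, got {self.x_sp}")


def fi_eval(params: FICurveParams, x):
    """Evaluate the sigmoidal F-I curve at ``x`` (scalar or array), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("fi_eval requires finite input activity")
    out = 0.5 * (1.0 + np.tanh((x - params.x_rev) / params.x_sp))
    return float(out) if out.ndim == 0 else out


_SIGNAL_KINDS = ("constant", "pulse", "sinusoid")
_SIGNAL_MODES = ("replace", "add")


@dataclass(frozen=True)
class InputSignal:
    """Time-dependent scalar drive applied to a background parameter.

    Kinds:

    * ``constant`` — ``baseline`` for all t.
    * ``pulse`` — smooth double-sigmoid
      ``baseline + amplitude*(S((t-t_on)/ramp) - S((t-t_off)/ramp))``
      with S the logistic function.
    * ``sinusoid`` — ``baseline + amplitude*sin(2*pi*frequency*t + phase)``.

    ``mode`` controls attachment semantics: ``"replace"`` substitutes the
    signal value for the per-cell baseline (identical across cells),
    ``"add"`` offsets each cell's heterogeneous baseline by the signal value.
    """

    kind: str
    baseline: float = 0.0
    amplitude: float = 0.0
    t_on: float = 0.0
    t_off: float = 1.0
    ramp: float = 0.1
    frequency: float = 1.0
    phase: float = 0.0
    mode: str = "replace"

    def __post_init__(self) -> None:
        if self.kind not in _SIGNAL_KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}; expected one of {_SIGNAL_KINDS}")
        if self.mode not in _SIGNAL_MODES:
            raise ValueError(f"unknown signal mode {self.mode!r}; expected one of {_SIGNAL_MODES}")
        if self.kind == "pulse":
            if self.ramp <= 0:
                raise ValueError("pulse ramp timescale must be positive")
            if not self.t_off > self.t_on:
                raise ValueError("pulse requires t_off > t_on")

    # -- constructors -------------------------------------------------
    @classmethod
    def constant(cls, baseline: float = 0.0, *, mode: str = "replace") -> "InputSignal":
        return cls(kind="constant", baseline=baseline, mode=mode)

    @classmethod
    def pulse(
        cls,
        baseline: float = 0.0,
        amplitude: float = 1.0,
        t_on: float = 2.0,
        t_off: float = 3.0,
        ramp: float = 0.1,
        *,
        mode: str = "replace",
    ) -> "InputSignal":
        return cls(
            kind="pulse",
            baseline=baseline,
            amplitude=amplitude,
            t_on=t_on,
            t_off=t_off,
            ramp=ramp,
            mode=mode,
        )

    @classmethod
    def sinusoid(
        cls,
        baseline: float = 0.0,
        amplitude: float = 1.0,
        frequency: float = 1.0,
        phase: float = 0.0,
        *,
        mode: str = "replace",
    ) -> "InputSignal":
        return cls(
            kind="sinusoid",
            baseline=baseline,
            amplitude=amplitude,
            frequency=frequency,
            phase=phase,
            mode=mode,
        )

    @property
    def timescale(self) -> float:
        """Fastest variation timescale of the signal (inf for constants)."""
        if self.kind == "pulse":
            return self.ramp
        if self.kind == "sinusoid" and self.amplitude != 0.0 and self.frequency != 0.0:
            return 1.0 / abs(self.frequency)
        return math.inf

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("signal time must be finite")
        if self.kind == "constant":
            out = np.broadcast_to(np.float64(self.baseline), t.shape).copy()
        elif self.kind == "pulse":
            from scipy.special import expit

            rise = expit((t - self.t_on) / self.ramp)
            fall = expit((t - self.t_off) / self.ramp)
            out = self.baseline + self.amplitude * (rise - fall)
        else:  # sinusoid
            out = self.baseline + self.amplitude * np.sin(
                2.0 * np.pi * self.frequency * t + self.phase
            )
        return float(out) if out.ndim == 0 else out


def standard_signal(kind: str) -> InputSignal:
    """The default fast drives used throughout the experiments.

    Both are fast relative to the unit relaxation time: a 1-time-unit pulse
    with a 0.1 ramp, and a unit-frequency sinusoid.
    """
    if kind == "pulse":
        return InputSignal.pulse(baseline=0.0, amplitude=1.0, t_on=2.0, t_off=3.0, ramp=0.1)
    if kind == "sinusoid":
        return InputSignal.sinusoid(baseline=0.0, amplitude=1.0, frequency=1.0, phase=0.0)
    if kind == "constant":
        return InputSignal.constant(0.0)
    raise ValueError(f"unknown input kind {kind!r}")


def _validate_corr(corr: np.ndarray, n: int) -> None:
    if corr.shape != (n, n):
        raise ValueError(f"corr must be {n}x{n}, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-12, rtol=0.0):
        raise ValueError("corr must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-9, rtol=0.0):
        raise ValueError("corr must have unit diagonal")
    off = corr[~np.eye(n, dtype=bool)]
    if off.size and np.max(np.abs(off)) >= 1.0:
        raise ValueError("off-diagonal noise correlations must lie in (-1, 1)")
    if n > 1:
        min_eig = float(np.linalg.eigvalsh(corr)[0])
        if min_eig < -1e-10:
            raise ValueError(f"corr must be positive semidefinite; min eigenvalue {min_eig:.3e}")


@dataclass(frozen=True)
class NetworkSpec:
    """Full static parameterization of a noise-driven coupled firing-rate network.

    Attributes
    ----------
    n_cells : int
        Number of cells.
    tau : (n_cells,) array
        Relaxation time constants, all positive.
    mu_bg : (n_cells,) array
        Baseline background input means.
    sigma_bg : (n_cells,) array
        Background noise amplitudes, nonnegative.
    corr : (n_cells, n_cells) array
        Instantaneous noise correlation matrix: symmetric, unit diagonal,
        positive semidefinite, off-diagonal entries in (-1, 1).
    coupling : (n_cells, n_cells) array
        Signed coupling strengths; entry (j, k) is the drive from cell k's
        firing onto cell j.
    fi : tuple of FICurveParams
        Per-cell transfer-curve parameters.
    inputs : mapping
        Optional time-varying drives keyed by ``"mu_bg"`` / ``"sigma_bg"``.
    """

    n_cells: int
    tau: np.ndarray
    mu_bg: np.ndarray
    sigma_bg: np.ndarray
    corr: np.ndarray
    coupling: np.ndarray
    fi: tuple
    inputs: Mapping[str, InputSignal] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = int(self.n_cells)
        if n < 1:
            raise ValueError("n_cells must be >= 1")
        object.__setattr__(self, "n_cells", n)
        for name in ("tau", "mu_bg", "sigma_bg"):
            arr = np.array(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got shape {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)
        if np.any(self.tau <= 0):
            raise ValueError("all time constants must be positive")
        if np.any(self.sigma_bg < 0):
            raise ValueError("noise amplitudes must be nonnegative")
        for name in ("corr", "coupling"):
            arr = np.array(getattr(self, name), dtype=float)
            if arr.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got shape {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)
        _validate_corr(self.corr, n)
        fi = tuple(self.fi)
        if len(fi) != n:
            raise ValueError(f"fi must have length {n}")
        for p in fi:
            if not isinstance(p, FICurveParams):
                raise TypeError("fi entries must be FICurveParams")
        object.__setattr__(self, "fi", fi)
        inputs = dict(self.inputs)
        for key, sig in inputs.items():
            if key not in ("mu_bg", "sigma_bg"):
                raise ValueError(f"signals may attach to 'mu_bg' or 'sigma_bg', not {key!r}")
            if not isinstance(sig, InputSignal):
                raise TypeError("attached inputs must be InputSignal instances")
        object.__setattr__(self, "inputs", inputs)

    # -- derived quantities -------------------------------------------
    @property
    def x_rev(self) -> np.ndarray:
        return np.array([p.x_rev for p in self.fi])

    @property
    def x_sp(self) -> np.ndarray:
        return np.array([p.x_sp for p in self.fi])

    @property
    def diffusion(self) -> np.ndarray:
        """Diffusion matrix D[j,k] = c_jk * sigma_bg_j * sigma_bg_k / (tau_j * tau_k)."""
        s_over_tau = self.sigma_bg / self.tau
        return self.corr * np.outer(s_over_tau, s_over_tau)

    def firing(self, x: np.ndarray) -> np.ndarray:
        """Vectorized per-cell F(x); ``x`` has cells on the last axis."""
        x = np.asarray(x, dtype=float)
        return 0.5 * (1.0 + np.tanh((x - self.x_rev) / self.x_sp))

    def with_inputs(self, **signals: InputSignal) -> "NetworkSpec":
        """Return a copy with the given signals attached (replacing existing ones)."""
        new_inputs = dict(self.inputs)
        new_inputs.update(signals)
        return dataclasses.replace(self, inputs=new_inputs)

    def without_inputs(self) -> "NetworkSpec":
        return dataclasses.replace(self, inputs={})


def eval_input(spec: NetworkSpec, t: float):
    """Effective background parameters (mu_tilde(t), sigma_tilde(t)) at time ``t``.

    With no attached signals this is the identity on the static fields.
    Raises if a modulated noise amplitude becomes negative.
    """
    if not np.isfinite(t):
        raise ValueError("time must be finite")
    mu_t = spec.mu_bg
    sigma_t = spec.sigma_bg
    sig = spec.inputs.get("mu_bg")
    if sig is not None:
        v = sig(t)
        mu_t = np.full(spec.n_cells, v) if sig.mode == "replace" else mu_t + v
    sig = spec.inputs.get("sigma_bg")
    if sig is not None:
        v = sig(t)
        sigma_t = np.full(spec.n_cells, v) if sig.mode == "replace" else sigma_t + v
        if np.any(sigma_t < 0):
            raise ValueError(f"modulated noise amplitude negative at t={t}")
    return np.asarray(mu_t, dtype=float), np.asarray(sigma_t, dtype=float)


def build_correlation_matrix(n_cells: int, entry_sd: float = 0.8, seed=None) -> np.ndarray:
    """Random noise-correlation matrix with approximately independent entries.

    Steps: (i) draw A with i.i.d. Normal(0, entry_sd^2) entries; (ii) scale by
    d_s(j) = 1/sqrt((A^T A)_jj); (iii) Cr = diag(d_s) A^T A diag(d_s).  The
    Gram construction makes the result symmetric PSD with unit diagonal.
    Degenerate draws (zero diagonal, or off-diagonal magnitudes at 1) are
    rejected and resampled.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if entry_sd <= 0:
        raise ValueError("entry_sd must be positive")
    rng = _as_generator(seed)
    for _ in range(100):
        a = rng.normal(0.0, entry_sd, size=(n_cells, n_cells))
        gram = a.T @ a
        d = np.diag(gram)
        if np.any(d == 0.0):
            continue
        ds = 1.0 / np.sqrt(d)
        corr = gram * np.outer(ds, ds)
        corr = 0.5 * (corr + corr.T)
        np.fill_diagonal(corr, 1.0)
        off = corr[~np.eye(n_cells, dtype=bool)]
        if off.size and np.max(np.abs(off)) >= 1.0 - 1e-6:
            continue
        return corr
    raise RuntimeError("failed to generate an admissible correlation matrix")


def sample_coupling(n_cells: int, l: float, seed=None) -> np.ndarray:
    """All-to-all coupling with i.i.d. Normal(0, (l/10)^2) entries (self included)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if l <= 0:
        raise ValueError("coupling scale l must be positive")
    rng = _as_generator(seed)
    return rng.normal(0.0, l / 10.0, size=(n_cells, n_cells))


def sample_network(n_cells: int, coupling_scale: float = 1.0, seed=None) -> NetworkSpec:
    """Draw a heterogeneous network from the reference parameter distributions.

    tau_j ~ Normal(1, 0.1^2) truncated to positive by resampling,
    mu_bg_j ~ Uniform[0,1] - 0.5, sigma_bg_j ~ Uniform[0,1] + 1,
    x_rev_j ~ Normal(0, 0.1^2), x_sp_j ~ 0.35*Uniform[0,1] + 0.05;
    correlation and coupling matrices via their dedicated samplers.
    Deterministic given ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if coupling_scale <= 0:
        raise ValueError("coupling_scale must be positive")
    rng = _as_generator(seed)
    tau = rng.normal(1.0, 0.1, size=n_cells)
    while np.any(tau <= 0):  # nonpositive draws are measure-tiny; keep the marginal
        bad = tau <= 0
        tau[bad] = rng.normal(1.0, 0.1, size=int(bad.sum()))
    mu_bg = rng.uniform(size=n_cells) - 0.5
    sigma_bg = rng.uniform(size=n_cells) + 1.0
    x_rev = rng.normal(0.0, 0.1, size=n_cells)
    x_sp = 0.35 * rng.uniform(size=n_cells) + 0.05
    corr = build_correlation_matrix(n_cells, seed=rng)
    coupling = sample_coupling(n_cells, coupling_scale, seed=rng)
    fi = tuple(FICurveParams(float(r), float(s)) for r, s in zip(x_rev, x_sp))
    return NetworkSpec(
        n_cells=n_cells,
        tau=tau,
        mu_bg=mu_bg,
        sigma_bg=sigma_bg,
        corr=corr,
        coupling=coupling,
        fi=fi,
    )
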