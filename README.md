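# ratemoments

Moment-closure statistics for heterogeneous, noise-driven, coupled
firing-rate networks.

Each cell `j` carries a scalar activity `x_j` obeying

```
tau_j dx_j/dt = -x_j + mu_bg_j(t) + sigma_bg_j(t) * eta_j(t) + sum_k g_jk F_k(x_k)
```

with background white noise that is instantaneously correlated across cells
(`<eta_j eta_k> = c_jk delta(t - t')`) and a sigmoidal transfer curve
`F(x) = 0.5 (1 + tanh((x - x_rev)/x_sp))`.  The package computes the complete
set of time-varying first- and second-order statistics — mean, variance and
covariance of both activity `x_j` and firing `F_j(x_j)` — three ways:

- **closure** (`ratemoments.integrate_closure`): a pairwise-Gaussian moment
  closure reduces the system to `N + N(N+1)/2` nonlinear ODEs for the means
  and raw second moments; firing statistics follow by a Gaussian change of
  variables.  The sigmoid expectation integrals are evaluated with an exact
  step-split scheme (analytic Gaussian step part plus a composite
  Gauss–Legendre rule graded to the sigmoid width), accurate to ~1e-10
  uniformly over the admissible parameters.
- **qss** (`ratemoments.qss_trajectory`): the quasi-steady-state baseline —
  the closure fixed point evaluated at each instant's drive values.
- **monte_carlo** (`ratemoments.simulate_ensemble`): ground truth —
  Euler–Maruyama ensembles with correlated noise increments, including the
  group-resampled error-band half-width `S` for every statistic.

Random network instances (time constants, drives, transfer curves, a Gram
random correlation matrix, dense Gaussian coupling at scale `l`) are drawn by
`ratemoments.sample_network`, and `ratemoments.coupling_sweep` reproduces the
accuracy-versus-coupling experiment via the average absolute error metric.

## CLI

```bash
# draw a 3-cell network at coupling scale 1 with a fast common pulse drive
ratemoments sample-network -n 3 -l 1.0 --seed 1 --input pulse -o net.yaml

# sanity-check it (correlation PSD, steady-state convergence)
ratemoments validate -c net.yaml

# run all three methods and write trajectory tables + error report
ratemoments simulate -c net.yaml -m all --t1 10 --dt-out 0.1 -o out/

# accuracy vs coupling scale
ratemoments sweep -n 10 -l 1,2,3,4 --input pulse -o sweep_out/
```

Trajectory tables are plain CSV with a versioned header comment and a JSON
metadata sidecar; every run writes its fully resolved configuration next to
its outputs, and a single `--seed` fans out into independent streams for
network sampling and Monte Carlo noise, so runs are exactly reproducible.

## Layout

| module | contents |
| --- | --- |
| `ratemoments.network` | `NetworkSpec`, F-I curves, input signals, random samplers |
| `ratemoments.expectations` | Gaussian sigmoid expectations E1/E2/M1, mixed moment, bivariate rate expectation, quadrature rules |
| `ratemoments.moments` | closure ODE right-hand side, integrator, activity→firing change of variables |
| `ratemoments.equilibrium` | steady-state solver and QSS baseline |
| `ratemoments.montecarlo` | Euler–Maruyama ensembles and error bands |
| `ratemoments.evaluation` | average absolute error, coupling sweep |
| `ratemoments.io`, `ratemoments.cli` | configuration/trajectory formats and the command line |
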