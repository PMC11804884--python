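# mbiselect

Variable selection for longitudinal studies that integrate covariates from
several sources (e.g. imaging, biofluid and cognitive panels merged into one
design matrix) when whole sources are missing *block-wise*: for any given
subject each source is either fully observed or fully absent, so the cohort
splits into a small number of missing patterns.

Complete-case analysis throws away most subjects in this setting, and
classical single imputation uses only the complete cases to train the
imputer. `mbiselect` instead imputes every incomplete pattern **multiple
times** — once for each viable combination of donor patterns and predictor
sources — and pools all resulting estimating equations.

## Model and estimator

For subject *i* in missing pattern *k* with `m` repeated measurements, the
marginal model is `E[Y_ij | X_ij] = mu(X_ij' beta)` with a known link
(identity or logit). With imputed design copies `X^(r)` the extended score
for copy *r* stacks, over working-correlation basis matrices `M_1..M_J`
(identity and off-diagonal exchangeable/AR-1 patterns),

```
g_ki^(r)(b) = D_r' A^{-1/2} M_j A^{-1/2} (Y_i - mu_i^(r)(b)),   j = 1..J,
```

avoiding any correlation nuisance parameters. Pattern averages of these
scores are stacked into one long moment vector `g(b)`, weighted by the
block-diagonal empirical second moment `C` of the subject-level scores
(Ledoit–Wolf-shrunk by default), and minimized as the penalized GMM
objective

```
S(b) = g(b)' C^+ g(b) + sum_j p_lam(|b_j|),
```

with the SCAD penalty `p_lam` (shape constant a = 3.7). Optimization is an
MM/Newton–Raphson scheme: the SCAD term enters through its local quadratic
approximation, giving damped updates
`b <- b - [F + D]^{-1} [M + D b]` with `M = 2 J'C^+ g`, `F = 2 J'C^+ J`.
The tuning parameter is selected by the extended BIC,
`EBIC = n log(RSS/n) + df {log n + 2*gamma*log p}` with `gamma = 0.5`, and
coefficients below 0.01 in magnitude are reported as exactly zero.

## Worked example

```python
import numpy as np
from mbiselect import ModelSpec, fit, fpr_fnr, scenario

ds = scenario("s1", rho=0.3, seed=1)   # 3 sources x 10 covariates, n=240
res = fit(ds.panel, ds.partition, ModelSpec())
print("selected:", res.support_names)
print("estimates:", np.round(res.beta_hat[res.support], 2))
print("fpr, fnr:", fpr_fnr(res.support, ds.true_support, ds.panel.p))
```

prints

```
selected: ['x1', 'x2', 'x11', 'x12', 'x16', 'x21', 'x22']
estimates: [0.83 2.3  0.38 2.11 0.06 0.67 2.38]
fpr, fnr: (0.041666666666666664, 0.0)
```

The generator's true model has nonzero coefficients (1, 2) on the first two
covariates of each source; the fit recovers all six (the smaller ones
visibly shrunk by the penalty at the selected tuning parameter) plus one
spurious covariate out of 24 irrelevant ones (FPR = 1/24 ≈ 0.042, FNR = 0).

The same pipeline is available from the shell:

```bash
mbiselect simulate --scenario s1 --rho 0.3 --seed 1 --out panel.csv
mbiselect fit --input panel.csv --layout panel.layout.yaml --out fit.json
mbiselect benchmark --scenario s1 --rho 0.3 --reps 100 --seed 1 --out results/
```

## Layout

- `mbiselect.data_model` — panels, source partitions, missing-pattern
  detection, CSV I/O
- `mbiselect.imputation` — imputation-combo enumeration and per-occasion
  least-squares imputation
- `mbiselect.scores` — working-correlation bases, extended scores, stacked
  moments and Jacobians
- `mbiselect.objective` — GMM weight, quadratic form, SCAD penalty
- `mbiselect.solver` — MM/Newton–Raphson path solver, EBIC selection,
  coefficient covariance
- `mbiselect.simulate` — synthetic multi-source longitudinal data with
  covariate-driven pattern assignment
- `mbiselect.benchmark` — replicated comparisons (proposed / complete-case /
  single-imputation) scored by FPR and FNR
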