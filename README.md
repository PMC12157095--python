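# covselect

Residual covariance structure selection for longitudinal marginal linear
models, guided by time-series diagnostics.

Repeated measurements on the same subject are correlated; a fixed-effects
model that ignores this leaves the correlation in its residuals. `covselect`
turns that observation into a workflow:

1. **simulate** — generate balanced longitudinal data with a *known*
   residual correlation structure (compound symmetry, AR(p) via the
   Yule-Walker equations, continuous-time kinds, optional per-occasion
   heteroscedastic variances).
2. **diagnose** — fit the mean structure alone by OLS, reshape residuals by
   subject × occasion, and characterize the leftover correlation with a
   lag profile (means of the off-diagonals of the residual correlation
   matrix) and a pooled partial autocorrelation function whose cutoff
   suggests an AR order.
3. **fit** — estimate the marginal model `y_i = X_i beta + eps_i`,
   `eps_i ~ N(0, sigma2 * D^{1/2} R(theta) D^{1/2})`, by ML or REML with
   `beta` and `sigma2` profiled out analytically and `theta` optimized in a
   boundary-safe unconstrained reparameterization.
4. **compare / run** — fit a menu of candidate structures, tabulate
   AIC/BIC/AICc, select a winner (BIC by default), and report whether it
   agrees with the residual diagnostics.

Supported correlation structures: independent, compound symmetry, AR(p)
(autocorrelations from the exact Yule-Walker system, extended by recursion),
continuous-time AR(1), exponential, Gaussian, linear, spherical, rational
quadratic, and fully unstructured.

## Library example

```python
from covselect import (CorrelationStructure, SimulationDesign,
                       simulate_dataset, run_pipeline)

design = SimulationDesign(n_subjects=150, times=tuple(range(1, 9)),
                          structure=CorrelationStructure("ar", (0.5, 0.3)),
                          sigma2=1.0, seed=1)
ds = simulate_dataset(design)
report = run_pipeline(ds, "time + group + age", estimation="REML")
print(report.selected["structure"])         # e.g. "AR(2)"
print(report.diagnostics["suggestion"])     # PACF-based suggestion
```

## CLI

The console script `covselect` mirrors the analysis stages:

```sh
covselect simulate --n-subjects 150 --times 1,2,3,4,5,6,7,8 \
    --structure ar --params 0.5,0.3 --seed 1 --out data.csv
covselect diagnose --data data.csv --fixed "time + group + age"
covselect fit --data data.csv --fixed "time + group + age" \
    --structure ar --order 2 --reml
covselect compare --data data.csv --fixed "time + group + age" \
    --structures cs,ar1,ar2,ar3,unstructured
covselect run --data data.csv --fixed "time + group + age" \
    --out report.json --format json
```

Exit codes: 0 success, 2 data-validation failure (missing values, duplicate
subject/time rows, rank-deficient design, ...), 3 when all candidate fits
failed to converge. Input data must be complete: handle missing values (for
example by multiple imputation) before loading.

## Conventions worth knowing

- REML is the default; information criteria use `n_eff = N` under ML and
  `n_eff = N - p` under REML, and `k` counts **all** estimated parameters
  (fixed effects, correlation parameters, variance weights, scale).
- The pooled PACF uses a fixed denominator `n*T` (biased but positive
  semidefinite autocovariances) and a `1.96/sqrt(n*T)` significance band;
  both are documented approximations for the many-short-series setting.
- Discrete structures (AR(p), CS, unstructured) require balanced,
  equispaced data; continuous-time structures accept irregular and
  unbalanced designs.
- Simulation covariate effect sizes are configurable placeholders, not
  values from any published cohort.
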