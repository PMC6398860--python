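# schoolhiv

Does attending secondary school causally protect young women against HIV,
or do the girls who stay in school simply differ from those who drop out?
`schoolhiv` implements a complete causal-inference battery for this
question on longitudinal seroconversion data of the kind collected by
population HIV surveillance in KwaZulu-Natal (annual test rounds, women
aged 15–24, household clusters), together with a synthetic-cohort
generator so every stage is testable without access to restricted
surveillance data.

## The models

The unit of analysis is the person-year of a previously HIV-negative
woman: a discrete-time hazard panel built from test histories with
interval-censored seroconversion dates. The core system is a recursive
bivariate probit

```
s_it = 1(x_it'δ + z_it'γ + u_it > 0)        (school attendance)
y_it = 1(x_it'π + s_it β  + ε_it > 0)       (seroconversion hazard)
(u, ε) ~ N(0, [[1, ρ], [ρ, 1]])
```

where `x` holds a constant, age and year dummies, urban/peri-urban
residence and two road distances, and `z` holds two exclusion
restrictions: an indicator of living closer than 7 km to the nearest
secondary school, and the distance gap between the nearest and
second-nearest school. ρ is the correlation between the unobserved
drivers of attendance and infection — selection on unobservables.

The battery around this system:

* **Descriptive table** — counts, seroconversion percentages, and
  stratum-versus-reference risk ratios with log-scale Wald intervals.
* **Probit association** — pooled probit of `y` on (`x`, `s`), household-
  cluster robust SEs, at-means discrete-change partial effect.
* **Imposed-correlation sensitivity grid** — the system without
  instruments, re-estimated with ρ fixed along a grid, plus the selection
  upper bound `Cov(xδ, xπ)/Var(xπ)` (the ρ implied if selection on
  unobservables equalled selection on observables).
* **Instrumented bivariate probit** — full-information ML over
  (δ, γ, π, β, atanh ρ), Wald test of ρ = 0.
* **Correlated random-effects probit** — pooled probit augmented with
  each woman's means of the time-varying covariates, absorbing
  time-constant heterogeneity.
* **Linear robustness suite** — linear probability model, individual
  fixed effects, LIML instrumental variables, and the
  coefficient-stability δ\* bound (how strong proportional selection on
  unobservables must be to drive the attendance coefficient to zero).

## Worked example

```python
from schoolhiv.cohort import default_config
from schoolhiv.pipeline import RunConfig, run_full_analysis

cfg = RunConfig(generator=default_config(n_individuals=3000, seed=0),
                seed=1, outdir="out")
summary = run_full_analysis(cfg)
```

With the calibrated default generator (attendance share ≈ 77%, annual
seroconversion ≈ 2.7%, true latent attendance effect **zero**, selection
ρ = −0.24), one run produced an estimation panel of 6,681 person-years
from 2,062 women and:

* probit attendance effect **−0.0103** (SE 0.0047, CI [−0.0195, −0.0011]) —
  a "significant protective association" that is pure selection, since the
  generator's causal effect is zero;
* sensitivity grid: effect −0.0103 at ρ = 0, crossing zero just above
  ρ = −0.10, +0.0147 at ρ = −0.30; selection upper bound −0.711;
* correlated random-effects probit: **−0.0056** (SE 0.0046) —
  insignificant once time-constant heterogeneity is absorbed;
* linear suite: OLS −0.0154, fixed effects −0.0116 (SE 0.0090,
  insignificant), LIML +0.084 with a wide interval, δ\* = 2.4 only in
  this draw's stable-coefficient configuration.

The qualitative pattern — a raw negative association that dissolves under
selection-aware estimators — is exactly what the battery is designed to
expose. All numbers are also written to `out/summary.json` and per-table
CSV files.

A command-line interface mirrors the library:

```bash
schoolhiv simulate --n 3000 --seed 0 --out data/
schoolhiv build-panel --tests data/test_histories.csv \
    --covariates data/covariates.csv --scheme main --out panel.csv
schoolhiv describe --panel panel.csv
schoolhiv report --seed 1 --out results/
```

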