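# Methods

This note documents the statistical models, the synthetic-cohort
generator, the numerical choices, and the limitations of `schoolhiv`.

## 1. Panel construction

The data model is a set of per-person HIV test histories (year, neg/pos)
plus per-person-year covariates. Seroconversion is interval-censored:
women are not tested every year, so infection can only be located between
the last negative and the first positive test.

Coding rules (scheme `main`):

* A woman enters the risk set the year **after** her first negative test:
  incidence is a hazard — a probability conditional on being previously
  negative — so the entry test establishes at-risk status and is not
  itself an incidence observation.
* Years covered by a later negative test are coded 0, including untested
  gap years before that negative (she was still negative when retested).
* The first positive year is coded 1, even when it follows a testing
  gap; the gap years between the last negative and the first positive
  are coded missing and excluded from estimation (counted in the
  exclusion log).

Scheme `strict` additionally codes the first positive year missing when
there is no negative test the year before; scheme `drop_uncertain`
removes such women entirely. The three schemes coincide on women with
no testing gaps, which the tests verify.

Sample restrictions: ages 15–24; secondary school not yet completed
(rows from the completion year onward dropped); rows after a woman's
seroconversion dropped. Surveillance entry can occur at age 14 or in the
year before the first round — entry-only events that make age-15 and
first-round person-years possible under the at-risk clock.

The estimation design holds a constant, age dummies (reference 16), year
dummies (reference = earliest year), urban and peri-urban dummies
(reference rural), and the two road distances: 21 columns on a full
panel. Ages with no events (typically 15) perfectly predict the outcome
under a full dummy set; the fitters refuse to run on such designs, and
`prune_separated` drops the offending dummy and its rows with logged
counts — the behaviour of standard probit software — only when
separation is exact.

## 2. Estimators

**Probit.** Own Newton implementation with analytic gradient and
Hessian; convergence requires gradient max-norm < 1e-6 and relative
log-likelihood change < 1e-10, and the `converged` flag reports what
actually happened. The log-likelihood uses `log_ndtr` throughout, so
indices of ±10 neither overflow nor truncate. Cluster-robust covariance:
sandwich with household-summed scores and a G/(G−1) small-cluster
factor on the meat (conventional finite-cluster practice). The reported
effect is the at-means discrete change Φ(x̄'π + β) − Φ(x̄'π) with a
delta-method SE; dummies are held at their means.

**Bivariate probit.** The bivariate normal CDF is computed from Owen's T
function (`scipy.special.owens_t`), accurate to ~1e-14 uniformly in the
correlation — the likelihood's curvature in ρ near the optimum demands
this, and the test suite checks it against 2-D adaptive quadrature. The
joint likelihood sums log orthant probabilities per observation,
optimized by BFGS with analytic gradients; ρ is parameterized as
atanh(ρ) so the optimization is unconstrained, and its CI is
back-transformed. Start values come from the two univariate probits with
ρ = 0. The covariance is a cluster sandwich whose bread is a central
finite-difference Hessian of the analytic gradient. The constrained
(under-identified) variant fixes ρ = φ and omits the instruments from
the attendance equation. When the observed information is not positive
definite at the optimum the partial-effect SE is reported as not
estimable rather than as a number.

The biprobit's attendance effect uses the same at-means discrete-change
convention as the probit, computed from the outcome equation — with an
endogenous regressor there are several defensible conventions, and this
one keeps the φ = 0 constrained fit exactly equal to the univariate
probit (verified to 1e-6 in the acceptance tests).

**Selection upper bound.** `Cov(xδ̂, xπ̂)/Var(xπ̂)` with both index
vectors from the φ = 0 under-identified system (the system the bound is
defined for) and attendance excluded from x. The sensitivity grid runs
from 0 downward and appends the bound as a flagged final entry; a
failure in one grid entry is recorded on that entry without aborting the
rest.

**Correlated random-effects probit.** Pooled probit with per-person
means of the time-varying columns appended (attendance and age dummies
by default). Means are computed over the retained estimation rows — the
estimation sample defines the panel. Time-constant columns (distances,
geography) are excluded as exactly collinear with their own means;
year-dummy means are excluded by default because ages advance
one-for-one with calendar years within person, making the two mean sets
near-collinear (configurable). This is a pooled device: no quadrature
random-effects integration is attempted.

**Linear suite.** OLS and the within (fixed-effects) estimator with the
same G/(G−1) cluster sandwich; the FE covariance is additionally scaled
for the absorbed person intercepts, and columns that demeaning leaves
collinear (again the age/year lockstep) are dropped via pivoted QR with
a note. LIML is the k-class estimator with κ the smallest eigenvalue of
the pencil (W'M_X W, W'M_XZ W), W = [y, s]; the just-identified case
collapses to standard IV (verified to 1e-8). The coefficient-stability
statistic uses the approximate proportional-selection adjustment

```
β*(δ) = β̃ − δ (β̇ − β̃)(r_max − R̃)/(R̃ − Ṙ)
```

(dots: treatment-only fit; tildes: controlled fit) and solves
β*(δ\*) = target, with r_max defaulting to min(1.3 R̃, 1); both the
r_max rule and the target are configurable, and a coefficient unmoved by
controls while R² rises is flagged unbounded rather than reported as a
number.

## 3. The synthetic-cohort generator

The generator emulates the structure the estimators assume, not any real
household roster: women in household clusters (geography and all four
distances are household-level), ages advancing deterministically with
calendar year, exit at 25, and the two-equation latent-index model with
bivariate-normal errors of correlation ρ plus an optional time-constant
individual effect loading on both equations.

Key choices:

* **Attendance persistence.** The cross-sectional latent index gives the
  entry-year state; afterwards the base re-entry/drop-out rates and the
  index are blended on the log-odds scale,
  p = expit(logit(base) + 0.5 · index), and the year's attendance is
  1(Φ⁻¹(p) + u > 0). Using u as the shock keeps the
  selection-on-unobservables channel alive in every person-year while
  the blend shifts the switch probabilities monotonically with the
  index. Setting the transition rates to `None` removes the persistence
  layer entirely, reducing attendance to the pure cross-sectional model.
* **Common random numbers.** All draws are made up-front in a
  coefficient-independent order, so configs differing only in
  coefficients see identical shocks — raising an instrument coefficient
  provably raises attendance among the affected group draw-for-draw.
* **Testing process.** The entry-year test is certain; later years are
  tested independently with probability `test_prob` (default 0.40,
  chosen so that roughly 40% of seroconverters have a negative test the
  year before their first positive). Tests after the first positive are
  discarded.
* **Distances.** Road distances are gamma with the observed means/SDs
  (7.27 ± 6.73 km and 1.45 ± 1.24 km); nearest-school distance is a
  truncated exponential on [0, 10] km with mean 2.6 km, putting most
  women within 2 km and a thin (~7%) tail beyond the 7 km instrument
  cut-off; the school gap is exponential. The source data's distance
  distributions are not published beyond range statements, so these are
  stylized.
* **Secondary completion** is a constant hazard (0.09/yr) for attenders
  aged ≥ 18 — a deliberately simple stand-in that exercises the
  completion restriction.

**Calibration.** The default config (`default_config`) was calibrated by
simulation so that the built estimation panel tracks the study's
descriptive rates: attendance share ≈ 77.6%, annual seroconversion
≈ 2.66%, measured re-entry ≈ 23.9% and drop-out ≈ 12.0% (all within ±2
percentage points over 20 seeds in the test suite). Its latent truth is
ρ = −0.24 with a **zero** causal attendance effect: the regime in which
the entire observed association is selection.

**Validation conditions.** `recovery_config` is the regime used for
Monte-Carlo estimator validation: no persistence layer, no individual
effect, full testing (so events are exactly dated), and deliberately
strong instruments (school-distance tail fattened to ~25% beyond 7 km,
larger instrument coefficients). Under these conditions the recursive
biprobit is exactly correctly specified; with ~20,000 person-years it
recovers ρ = −0.24 within ±0.1 and covers the true β in well over 85% of
replications. Under the *default* config the biprobit is deliberately
misspecified in two realistic ways — attendance persistence warps the
first-equation index, and testing gaps misdate events relative to the
attendance covariate — so its ρ̂ can wander far from the latent truth on
a given draw; that is a property of the design being emulated, not of
the optimizer, and it is why the validation regime exists.

## 4. What the tests do and do not show

Passing tests show the estimators do what their theory promises **when
their assumptions hold**, and that the battery's qualitative logic —
naive association under selection, recovery with instruments, bias
removal by within-person devices — plays out on data with the assumed
structure. They do not show that any of this holds on real surveillance
data, where errors need not be bivariate normal, instruments need not be
excludable, attendance is self-reported, and testing is not missing at
random. The generator also omits ART scale-up, migration, partner
networks, and spatial structure beyond household clustering.

Problem sizes in the test suite (50-replication Monte Carlos at 8,000 to
20,000 person-years; 1,000-draw property checks) were chosen to make the
statistical assertions sharp at interactive runtimes; the acceptance
script uses the same conditions at smaller replication counts.
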