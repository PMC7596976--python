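# Methods

## Model

Observed mortality after diagnosis is modelled additively,

    lambda_O(t | z) = lambda_E(t | z) + w(a + t, x) * lambda_P*(a + t | z_D),

with a piecewise-constant baseline excess hazard over K follow-up
intervals and log-linear covariate effects,

    lambda_E(t | z) = sum_k exp(tau_k) I_k(t) * exp(beta' z).

The life-table weight `w` defines the model family:

| kind         | w(a + t, x = m)            | extra parameters |
|--------------|----------------------------|------------------|
| `esteve`     | 1                          | none             |
| `touraine`   | alpha_m                    | M                |
| `breakpoint` | alpha_mb, b: age segment   | M (B + 1)        |

Attained-age segments are left-closed right-open, `[eps_{b-1}, eps_b)`;
a subject whose follow-up crosses a breakpoint changes segment at the
crossing.  Multipliers are estimated on the log scale
(`alpha = exp(alpha~)`), which enforces positivity and gives Wald
intervals that exponentiate cleanly.

### Likelihood

With `delta_i` the death indicator, the log-likelihood is

    l(psi) = sum_i [ -Lambda_E(t_i | z_i)
                     - sum_b alpha_{x_i, b} * Lambda*_{P,b}(t_i)
                     + delta_i log( lambda_E(t_i | z_i)
                                    + alpha_{x_i, b(a_i + t_i)} lambda_P*(a_i + t_i) ) ]

where `Lambda*_{P,b}(t_i)` is the portion of the cumulative population
hazard accrued while the subject's attained age lay in segment b.  This
segment-wise weighting makes the survival term the exact integral of the
hazard.  An alternative convention applies the final segment's
multiplier to the *total* cumulative population hazard; it is available
as `cumulative="literal"` on the model specification and coincides with
the default whenever no follow-up crosses a breakpoint (in particular
for B = 0).  The segment-wise form is the default because with the
literal form the density does not integrate the hazard when follow-up
crosses a breakpoint.

The analytic score has the usual counting-process structure
(`-cumulative + delta * hazard-share`) in all three blocks
(beta, tau, alpha~) and is verified against central finite differences
in the test suite at 1e-5 relative tolerance.

### Life-table arithmetic

A life table is a grid of annual hazards on 1-year age x calendar-year
cells (optionally stratified, e.g. by sex).  Attained age and calendar
year advance together with follow-up (the diagonal of the Lexis
diagram); cell membership is by floor of each coordinate.  All
cumulative hazards are computed by exact piecewise integration across
every age-cell, year-cell and breakpoint crossing — no quadrature — so
the subject-level cumulative-hazard path is piecewise linear and any
breakpoint split of it is obtained by interpolation.  Lookups beyond the
tabulated age or year carry the boundary cell forward: simulated
subjects can outlive the last tabulated age, and a rate of the right
order is preferable to an error.

Input tables are long-format CSV (`age, year[, sex], rate`), or annual
death probabilities `qx` converted by `-log(1 - q)` with the `qx`
dialect.  The bundled US male 1990 table was exported from the
`survexp.us` ratetable of the R `survival` package (daily hazards,
multiplied by 365.241):

```r
library(survival)
m <- survexp.us[, "male", "1990"] * 365.241
write.csv(data.frame(age = as.integer(dimnames(survexp.us)$age),
                     year = 1990L, rate = as.numeric(m)),
          "us_male_1990.csv", row.names = FALSE, quote = FALSE)
```

### Fitting

* Optimizer: BFGS with the analytic score; convergence when the score
  max-norm is below 1e-6 (relaxed to 1e-4 for the convergence flag); up
  to 3 jittered restarts from the initial point on failure.
* Initial values: beta = 0, alpha~ = 0, tau_k = log crude death rate
  per interval floored at 1e-4/year.
* Baseline cuts: user-supplied, or by default K = 5 intervals with cut
  points at quintiles of the observed death times and the last cut at
  the maximum follow-up, giving every interval a comparable number of
  events.
* Covariance: inverse of the observed information obtained by central
  finite differences of the analytic score at the optimum (step
  `1e-5 * (1 + |psi|)`), symmetrized.  95% intervals for EHR = exp(beta)
  and alpha = exp(alpha~) exponentiate Wald intervals on the log scale.
* AIC = 2 * (free parameters) - 2 * loglik, exactly.
* Identifiability guards: a baseline interval or a (level, segment)
  cell without person-time raises an error naming the cell;
  non-convergence is flagged on the result, not raised.

### Breakpoint search

The candidate grid is the interior deciles (10%..90% quantiles) of the
attained age at end of follow-up over all subjects — attained age is the
axis on which the correction acts, and published breakpoint estimates
for this kind of model are attained ages.  For B breakpoints all C(9, B)
location sets are fitted and the lowest AIC wins; location sets that
leave a (level, segment) cell without person-time are recorded as
skipped rather than fitted with an unidentifiable multiplier.  Ties
break toward the lexicographically earlier location tuple, and the AIC
choice between the best single- and two-breakpoint fits ("model 4")
breaks ties toward the single breakpoint — the more parsimonious model.
Both rules make the scan fully deterministic.

## Simulation design

Each replicate draws n = 2000 subjects:

* age at diagnosis from a mixture of uniforms on [30, 65), [65, 75),
  [75, 85) with weights (0.25, 0.35, 0.40);
* a categorical `x` with P(x = 1) = 0.9 for the binary scenarios
  (three levels with probabilities (0.1, 0.1, 0.8) for scenario F);
* an excess death time by inverse transform from a power generalized
  Weibull baseline, `Lambda0(t) = (1 + (lambda t)^k)^theta - 1` with
  (k, lambda, theta) = (2, 0.2, 0.5), under proportional effects
  `exp(beta_a * (a - 70)/10 + beta_x * x)` with beta_a = 0.3,
  beta_x = -0.2;
* an other-cause death time by exact piecewise-exponential inversion of
  the *complete* life table (the incomplete table times the scenario's
  per-level multipliers);
* administrative censoring at 6 years; observed time is the minimum.
  All subjects are men diagnosed in the same calendar year (1990).

Fitting always uses the *incomplete* table, so the scenarios probe
mis-specified background mortality: A no mismatch, B proportional
(defaults 1.5 / 0.8), C crossover (step 0.7<->1.4 at age 75), D
converging linearly to 1 with age, E diverging linearly from 1 with age,
F three proportional levels.  The mismatch *shapes* follow the scenario
definitions; the *magnitudes* are package defaults chosen to be of the
order seen in deprivation and ethnicity life-table gaps (tens of
percent), and are configurable.

Two generator details are deliberate modelling choices on our part
because no canonical values exist for them: the exact three-parameter
generalized-Weibull parameterization (we use the power generalized
Weibull, which reduces to the ordinary Weibull at theta = 1), and the
age scale in the linear predictor (we use (a - 70)/10; with raw age in
years a log-hazard slope of 0.3 per year would make survival
degenerate).  Both choices are pluggable through `SimConfig`.  They give
a censoring fraction of about 44-46% under the no-mismatch scenario on
the US male 1990 table, close to the ~40% the protocol targets.

Replicate streams are spawned from a single master seed
(`numpy.random.SeedSequence`), so every store is bit-for-bit
reproducible from its manifest.

### What the generator does and does not emulate

It reproduces the joint structure that matters for the estimators —
age-dependent background mortality read from a real table, additive
cause structure, covariates affecting both components, administrative
censoring.  It does not emulate calendar-period effects (the year is
fixed), delayed entry/left truncation, informative censoring, or
covariate measurement error; conclusions from passing tests transfer to
real registry data only to the extent those features are absent or
ignorable.

## Performance criteria

For replicate estimates theta^ of a true value theta: bias =
mean(theta^) - theta; relative bias = bias / theta (undefined and
reported as missing at theta = 0); ECR = percentage of 95% intervals
containing theta; RMSE = sqrt(mean((theta^ - theta)^2)).  Non-converged
replicates are excluded and counted.  AIC selection frequencies are the
share of replicates in which each model of an explicit comparison set
attains the strictly lowest AIC, ties resolving to the model listed
first (list more parsimonious models first).

## Problem sizes

The test suite and the acceptance script run the full pipeline at
reduced replicate counts — 50-250 replicates for the performance and
coverage checks and about a dozen replicates for the 45-fit breakpoint
scans — chosen so the whole suite completes in minutes on one core
while keeping Monte-Carlo bands (binomial 99% bands for coverage and
selection, 3-standard-error bands for means) wide enough to be decided
honestly at those counts.

## Known limitations

* A single categorical additional variable; no continuous or multiple
  mismatch variables (a frailty or latent-class treatment is out of
  scope).
* Piecewise-constant baseline and piecewise-constant corrections; no
  splines, no time-dependent covariate effects.
* No left truncation; censoring is administrative only.
* The breakpoint scan refits C(9, B) models per B; at B = 2 this is 36
  maximum-likelihood fits per dataset, a few seconds at n = 2000.
* Wald intervals on log alpha can be poor when a level x segment cell
  contains little person-time; the empty-cell guard catches only the
  extreme case.
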