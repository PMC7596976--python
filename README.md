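# exhaz

Excess-hazard (relative survival) regression with correction of an
inaccurate life table through attained-age breakpoints.

## The problem

Population-based cancer survival studies estimate *net survival* by
splitting the observed mortality of a cohort into an excess hazard
(attributable to the disease) and an expected hazard read from a
population life table:

    lambda_O(t | z) = lambda_E(t | z) + lambda_P*(a + t | z_D)

where `a` is age at diagnosis, `t` time since diagnosis, and `z_D` the
demographic variables (age, sex, calendar year) the life table is
stratified by.  When a variable `x` that *does* affect background
mortality — deprivation, occupation, ethnicity — is missing from the life
table, the expected hazard is wrong and the estimated covariate effects
on the excess hazard are biased.

`exhaz` fits three nested corrections by joint maximum likelihood:

* **Model 1** (classical additive excess hazard): the life table is
  trusted, `lambda_E(t|z) = sum_k exp(tau_k) I_k(t) exp(beta' z)` with a
  piecewise-constant baseline over K follow-up intervals.
* **Model 2** (proportional correction): the life-table hazard of a
  subject with `x = m` is rescaled by a multiplier `alpha_m > 0`,
  estimated jointly with `(beta, tau)`.
* **Model 3** (breakpoint correction): the multiplier additionally
  depends on attained age through breakpoints `eps_1 < ... < eps_B`,
  `alpha_mb` applying while `eps_{b-1} <= a + t < eps_b`.  This drops the
  proportional-mismatch assumption, which fails for instance when two
  groups' background-mortality curves cross at old ages.

Models 1 and 2 are exact special cases of Model 3 (`alpha == 1`, `B = 0`),
so the models share one likelihood and one fitting routine.  Breakpoint
locations are chosen by scanning the interior deciles of the attained-age
distribution (9 candidates, hence 9 single-breakpoint and C(9,2) = 36
two-breakpoint location sets) and keeping the set with the lowest AIC;
choosing between the best single- and two-breakpoint fits by AIC is
"Model 4".

The package also contains the Monte-Carlo machinery to study these
estimators: a cohort generator (generalized-Weibull excess times,
life-table other-cause times, administrative censoring at 6 years) under
six background-mismatch scenarios, and performance summaries (bias,
relative bias, empirical coverage rate, RMSE, AIC selection
frequencies).

## Worked example

Fit the proportional correction to a simulated cohort in which level
`x = 1` truly has 1.5x the life-table background mortality:

```python
import numpy as np
import exhaz as ex
from exhaz.simulate import ScenarioSpec, _const

table = ex.load_us_male_1990()                     # bundled US male 1990 rates
scen = ScenarioSpec("demo", (_const(1.0), _const(1.5)), (0.1, 0.9))
cfg = ex.SimConfig(n_subjects=2000)
data, truth = ex.assemble_cohort(2000, cfg, scen, table, np.random.default_rng(42))

spec = ex.model_spec_for(data, cfg, scen, "touraine")
res = ex.fit(data, table, spec)                    # fitted against the *unstratified* table
print(ex.wald_summary(res)[["term", "kind", "estimate", "lo", "hi"]])
print(f"loglik={res.loglik:.1f}  AIC={res.aic:.1f}")
```

Output:

```
               term   kind  estimate        lo        hi
0             age_c    EHR  1.303661  1.136305  1.495666
1               x_1    EHR  0.859872  0.479099  1.543270
2  alpha[x=0,seg=0]  alpha  1.122773  0.575031  2.192264
3  alpha[x=1,seg=0]  alpha  1.723259  1.355158  2.191348
loglik=-3234.0  AIC=6486.0
```

The excess-hazard ratios are consistent with the generating effects
(`exp(0.3) = 1.35` per decade of age, `exp(-0.2) = 0.82` for `x = 1`,
both inside the intervals), the correction factor for `x = 1` has the
injected 1.5 mismatch inside its interval, and the factor for the
reference level straddles 1.  Averaged over replicates the `x = 1`
factor centers on 1.5 (the acceptance script reports this).

The same workflow is available from the shell:

```sh
exhaz make-fixture --kind gompertz-like --out lt.csv
exhaz simulate --scenario A --N 10 --n 2000 --seed 7 --lifetable lt.csv --models 1,2
exhaz evaluate estimates.csv --compare 1,2
exhaz fit cohort.csv --lifetable lt.csv --model breakpoint --breakpoints 83,88 \
    --covariates age_c,x_1 --levels 2
exhaz scan-breakpoints cohort.csv --lifetable lt.csv --B 2 --covariates age_c,x_1
```

Every command writes a manifest (options + seed + version) next to its
outputs.

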