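# riskuq

Uncertainty quantification for individual risk estimates from clinical
prediction models.

## The problem

A clinical prediction model maps an individual's predictor values to a
probability of a health outcome — a risk of death after traumatic brain
injury, of prostate cancer, of cancer recurrence. Almost all such models
report a single point estimate of that risk and hide the *epistemic*
uncertainty that comes from having developed the model on one finite sample:
had a different development sample of the same size been drawn, the model —
and the risk it assigns to the same individual — could differ substantially,
especially at small development sample sizes. `riskuq` is a toolkit for
model developers and evaluators who want to quantify, summarise, and present
that uncertainty:

* **Uncertainty distributions and intervals per individual.** Bootstrap the
  development cohort (n-out-of-n with replacement), refit the *entire*
  model pipeline — including penalty tuning and variable selection — on each
  resample, and read off the distribution of predicted risks for an
  individual. Or, for unpenalised logistic models, draw parameter vectors
  from the multivariate normal defined by the estimates and their
  variance-covariance matrix (the Laplace approximation to a Bayesian
  posterior) and push them through the logistic link. Summaries are
  equal-tailed percentile intervals (default 50% and 95%) and
  uncertainty-aware point estimates (mean / median / mode of the
  distribution, alongside the plug-in value).

* **Decisions under uncertainty.** With a four-outcome utility table
  (u_TP, u_FP, u_FN, u_TN), the expected utility difference of acting at
  risk p is ΔU(p) = p·B − (1−p)·H with B = u_TP − u_FN and H = u_TN − u_FP,
  which is zero exactly at the implied threshold t = H/(H+B). Because ΔU is
  linear, the uncertainty-aware decision is "act" iff the *mean* of the
  uncertainty distribution is ≥ t — which can flip the plug-in decision for
  individuals near the threshold. The package also reports the share of the
  distribution on either side of t, a classification instability index, and
  whether each interval straddles the threshold.

* **Model instability simulation.** A known logistic truth (one genuine
  predictor X ~ N(0, 4), intercept 0, unit slope, ten standard-normal noise
  variables) generates development cohorts of 50–5000 individuals; lasso
  models fitted to them, bootstrapped, and applied to nine reference
  individuals with true risks 0.1–0.9 show prediction uncertainty that can
  span nearly the whole [0, 1] axis at n = 50 and shrinks steadily with n.

* **Calibration curves with confidence bands at evaluation.** On an
  evaluation cohort, a smoothed calibration curve (logistic regression of
  the outcome on a restricted cubic spline of logit(estimated risk), or
  loess with bootstrap bands) with pointwise confidence intervals gives
  risk-conditional uncertainty: the band at estimated risk 0.8 is the
  uncertainty interval for the true risk of everyone sharing that estimate,
  renderable as "in a group of 100 individuals like you, between about
  78 and 100 will …". Subgroup curves and band-width comparisons support
  fairness checks.

## Worked example

```python
import numpy as np
from riskuq import (DGPSpec, ModelSpec, generate_population,
                    bootstrap_ensemble, sample_bootstrap_distribution,
                    summarize, classify_with_instability, tracked_individuals)

dgp = DGPSpec(seed=3)                      # X ~ N(0,4), 10 noise variables
cohort, _ = generate_population(dgp, n=500, seed=3)
spec = ModelSpec(penalty="lasso", seed=5)  # 10-fold CV over 100 penalties
ens = bootstrap_ensemble(cohort, spec, B=500, seed=7)

(person,) = tracked_individuals([0.3], dgp)   # true risk exactly 0.30
dist = sample_bootstrap_distribution(ens, person.x, "P=0.3")
s = summarize(dist)
print(f"plug-in {ens.original.predict_risk(person.x):.3f}  "
      f"mean {s.mean:.3f}  95% [{s.intervals[0.95].lower:.3f}, "
      f"{s.intervals[0.95].upper:.3f}]")

d = classify_with_instability(dist, t=0.2)
print(f"decision {d.decision}  P(risk >= 0.2) = {d.prob_above:.2f}  "
      f"instability {d.instability_index:.2f}")
```

prints (seed-exact; the 500 full-pipeline refits take a few minutes):

```
plug-in 0.372  mean 0.360  95% [0.304, 0.421]
decision act  P(risk >= 0.2) = 1.00  instability 0.00
```

The individual's true risk is 0.30; the model's plug-in estimate is 0.372,
the uncertainty-aware (mean) estimate 0.360, and the 95% percentile interval
[0.304, 0.421] — an n = 500 model overestimates this individual and its
uncertainty interval misses the truth, yet the interval sits entirely above
a 0.2 decision threshold, so the *decision* to act is stable (instability
index 0.00: no bootstrap refit puts this individual below the threshold).

The same machinery is available from a CLI
(`riskuq fit | bootstrap | predict | decide | calibrate | simulate-instability |
report`); see `riskuq --help`.

## Acceptance script

`scripts/acceptance.py` recomputes from scratch, by running the package:

* **t2** — the mean true event probability of 1,000,000 individuals drawn
  from the default instability-experiment data-generating process (expected
  0.5 by the symmetry of the DGP);
* **t3** — the empirical coverage (%) of 95% equal-tailed percentile
  bootstrap intervals for five fixed covariate profiles under a correctly
  specified two-predictor logistic model (150 replicates, development
  n = 1000, 400 bootstrap refits each).

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The run takes a couple of minutes on one CPU, almost all of it in the
~60,000 logistic refits of t3.
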