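# Methods

## Scope and model

`riskuq` quantifies the epistemic (sampling) uncertainty of individual risk
estimates from binary-outcome logistic prediction models. The model class is
deliberately narrow — unpenalised and L1-penalised (lasso) logistic
regression — but the bootstrap engine only needs a fit/predict contract, so
the uncertainty machinery is model-agnostic in structure. Time-to-event and
multinomial outcomes, tree ensembles, full Bayesian MCMC, conformal
prediction, multiple imputation, and model updating/recalibration are out of
scope.

## Fitting

**Unpenalised logistic regression** is maximum likelihood via statsmodels'
Newton/IRLS. The parameter variance-covariance matrix (inverse observed
information) is kept on the fitted model; it is the input to the parametric
uncertainty route. Perfect separation is detected (non-convergence, or any
standardized coefficient magnitude above 30) and raised as a convergence
error — huge unstable coefficients are never returned silently.

**Lasso logistic regression** uses a hand-rolled proximal-Newton coordinate
descent in the glmnet convention: objective `(1/n)·deviance/2 + λ‖β‖₁`,
predictors standardized internally to unit variance, intercept never
penalised, coefficients reported back on the original scale. The solver is
hand-rolled because the scikit-learn L1 solvers available here either
penalise the intercept (liblinear) or leave it biased under strong penalties
(saga's stopping rule), which breaks the exact identity that a fully shrunk
fit has slopes 0 and intercept logit(mean(y)); the test suite cross-checks
the solver against saga at moderate penalties, where saga is reliable
(agreement ~1e-10). Convergence uses the glmnet-style criterion (maximum
weighted squared coefficient change per unit weight < 1e-7; 1e-9 for the
final refit).

**Tuning**: K-fold stratified cross-validation (default K = 10) minimising
held-out binomial deviance over a warm-started logarithmic path of 100
penalties from λ_max (smallest penalty that shrinks all slopes to zero) down
to `1e-4·λ_max` (the glmnet default ratio for n > p). Fold assignment is the
only stochastic step in fitting and is driven by `ModelSpec`'s mandatory seed,
so refits are bit-reproducible. No covariance matrix is reported for
penalised fits: a post-selection covariance is not well defined, so
parametric sampling is restricted to unpenalised models.

**Missing data** are rejected at load time (rows dropped, counts logged),
never imputed.

## Uncertainty distributions

**Bootstrap route** (default, any fitter): n-out-of-n resampling with
replacement; each of the B members refits the *full pipeline*, including
penalty tuning, so selection uncertainty is captured. Resamples with a
single outcome class are redrawn (cap 100 per member, then error) and the
redraw count is recorded — refusal is safer than refitting degenerate data.
Default B = 1000; larger ensembles (e.g. 10 000) are a parameter. One master
seed spawns independent per-member substreams (`numpy.random.SeedSequence`),
so ensembles are reproducible regardless of execution order. An individual's
uncertainty distribution is simply the B member predictions at their
covariates.

**Parametric route** (unpenalised only): S draws from
MVN(estimates, varcov) mapped through `expit((1,x)·θ)`. This is the Laplace
(normal) approximation to the Bayesian posterior under a flat prior — an
approximation, not an MCMC implementation. Its percentile intervals converge
to the closed-form Wald interval `expit(lp ± z·se(lp))` as S → ∞, which the
tests exploit as an oracle (tolerance 0.005 at S = 1e5).

**Summaries**: equal-tailed percentile intervals (default levels 0.50 and
0.95) — not BCa, matching intervals read directly off sampled predictions.
Mean and median are the usual sample statistics. The mode is the midpoint of
the fullest bin of a fixed 100-bin histogram on [0, 1], ties broken toward
the bin nearest the mean (the mode of a finite sample needs a convention;
this one is deterministic and scale-free). All sampled risks are inside
(0, 1) by construction — the linear predictor is clipped at ±36 before
expit, which is the widest range where double-precision expit stays strictly
inside the unit interval — so no post-hoc clipping of risks ever occurs.

## Decisions at a risk threshold

The four-outcome utility table (u_TP, u_FP, u_FN, u_TN) gives
ΔU(p) = p·B − (1−p)·H, B = u_TP − u_FN > 0, H = u_TN − u_FP ≥ 0, zero
exactly at t = H/(H+B). The normalized form built from a threshold t
(u_TP = 1, u_FN = u_TN = 0, u_FP = −t/(1−t)) is the default utility scale;
absolute utilities are configuration because real scales are
application-specific. Ties at p = t decide "act" (a risk *at* the threshold
triggers the action). Expected utility over a distribution equals ΔU(mean)
by linearity — asserted at runtime — so the uncertainty-aware decision rule
is "mean ≥ t". The classification instability index is the distribution mass
on the opposite side of t from the decision taken; the "conclusive" flag
defaults to 0.9 majority mass (a 60/40 split is the canonical inconclusive
case; the cut-off is configurable, not canonical).

## Calibration at evaluation

Estimated risks are clipped into [1e-6, 1 − 1e-6] (counts logged) before
logit. The default smoother is a logistic GLM of the outcome on a
restricted cubic spline (Harrell basis) of logit(estimated risk), 4 knots at
quantiles 0.05/0.35/0.65/0.95 (3–7 knots supported). Pointwise bands are
normal-theory on the linear predictor, mapped through expit, so curve and
band live in [0, 1] with no clipping. Bands are pointwise, not simultaneous:
they support per-risk-group statements, and joint coverage over the whole
curve is *not* claimed. A loess alternative with percentile-bootstrap bands
(default 200 resamples) is provided as a sensitivity check. Queries beyond
the observed estimated-risk range raise an extrapolation error reporting the
range — tails with no data cannot support an interval. Interpolation between
grid points is linear on the logit scale. Subgroup curves are fitted
per group; groups failing the preconditions (n < 20, one-class outcomes,
constant risks) are listed in a skipped-groups report, and band widths are
compared as the mean pointwise width over the common (intersection) grid.

## Synthetic data

The package ships two generators instead of any real cohort; both state a
fixed world and are not tuned.

* **Instability DGP**: one genuine predictor X ~ Normal(0, variance 4) —
  the N(0, 4) notation is read as variance 4 (SD 2), the standard
  parameterisation — with intercept 0 and unit slope, plus 10 independent
  Normal(0, 1) noise variables with true coefficient 0. The population mean
  true risk is 0.5 by symmetry. Reference individuals sit at
  X = logit(P)/slope with all noise coordinates 0, so their true risk is P
  to machine precision; the default nine use P = 0.1, …, 0.9. The default
  sample-size grid is 50, 100, 385, 500, 1000, 5000. The uncertainty
  distribution is realised by bootstrap refits (B = number of sampled risks
  by default), the frequentist reading of "sampled from the uncertainty
  distribution".
* **Low-prevalence cohort emulator** (`generate_gusto_like`): eight mixed
  predictors — four standard-normal continuous (coefficients 0.9, −0.4,
  0.35, −0.15) and four binary with prevalences 0.15/0.15/0.17/0.39
  (coefficients 0.8, 0.3, 0.4, 0.35) — chosen once as a realistic
  acute-MI mortality shape (age dominant, blood pressure protective,
  haemodynamic class strong). The intercept is solved by bisection on the
  drawn predictor matrix so the cohort mean true risk equals the requested
  prevalence (default 2851/40830 ≈ 0.0698) to 1e-6; outcomes are Bernoulli
  at the true risks. The generator emulates *shape* (low prevalence, mixed
  predictors, large n) only; it reproduces no real dataset, so green tests
  establish correct low-prevalence behaviour of the machinery, not any
  published number.

What the generators do **not** emulate: predictor correlation, measurement
error, missingness, case-mix drift between development and evaluation, and
non-logistic truths. Green tests therefore establish internal correctness
and statistical behaviour under a correctly specified world, not robustness
to misspecification.

## Numerical choices

* Linear predictors clipped at ±36 before expit (strict (0,1) in double
  precision); lasso IRLS weights floored at 1e-5.
* Percentile intervals use `numpy.quantile`'s default linear interpolation.
* The coverage experiment's five profiles solve logit(P) along the first
  predictor with the second at 0, P ∈ {0.1, 0.3, 0.5, 0.7, 0.9}.
* Bisection (Brent) tolerance for the prevalence intercept: 1e-9 on the
  intercept, giving mean-risk error well below 1e-6.
* All seeds are 31-bit, derived from a master seed via `SeedSequence`.

## Known limitations

* Bootstrap refits assume i.i.d. rows; no cluster/multilevel bootstrap.
* The parametric route understates uncertainty when the model is
  misspecified (it trusts the information matrix); the bootstrap is the
  safer default.
* Percentile intervals can undercover slightly at small n and extreme true
  risks (a known property of the percentile bootstrap, visible in the
  coverage experiment at the 0.1/0.9 profiles).
* Calibration bands are pointwise; simultaneous statements about the whole
  curve are not supported.
* The heavy test paths scale their simulations down (reduced B, lighter CV
  grids) to run on one CPU in minutes; the defaults users get are the full
  sizes documented above.
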