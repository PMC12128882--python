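"""Synthetic data generators and the model-instability simulation.

The instability experiment: simulate a development cohort from a known
logistic truth with one genuine predictor X ~ Normal(0, variance 4)
(intercept 0, unit slope, so the population mean true risk is 0.5 by
symmetry) plus ten standard-normal noise variables with zero coefficients;
fit a lasso logistic model; and read off the bootstrap uncertainty
distribution of predicted risk for nine reference individuals whose true
risks are 0.1, ..., 0.9. Repeating this across development sample sizes
50, 100, 385, 500, 1000, and 5000 shows uncertainty shrinking with n —
at n = 50 the sampled predictions for a mid-risk individual can span nearly
the whole [0, 1] axis.

A second generator emulates the shape of a large thrombolytic-trial cohort
(binary 30-day mortality, prevalence around 7%, eight mixed
continuous/binary predictors) so that low-prevalence behaviour is testable
without any external dataset. All coefficients are fixed and documented; the
intercept is solved by bisection so the population mean risk equals the
requested prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._utils import safe_expit, logit, spawn_seeds
from .cohort import CohortData
from .exceptions import InputError
from .logistic import ModelSpec, fit_model
from .uncertainty import (BootstrapEnsemble, RiskDistribution,
                          bootstrap_ensemble, sample_bootstrap_distribution)

DEFAULT_N_GRID = (50, 100, 385, 500, 1000, 5000)
DEFAULT_TRACKED_RISKS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class DGPSpec:
    """Data-generating process: one genuine predictor plus pure noise.

    X ~ Normal(0, x_variance) with a real coefficient ``slope``; ``n_noise``
    independent Normal(0, noise_variance) variables with true coefficient 0;
    outcome ~ Bernoulli(expit(intercept + slope * X)). The default
    (intercept 0, slope 1, variance 4 — i.e. SD 2) gives a population mean
    true risk of 0.5 by symmetry.
    """

    slope: float = 1.0
    intercept: float = 0.0
    x_variance: float = 4.0
    n_noise: int = 10
    noise_variance: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.x_variance <= 0:
            raise InputError("x_variance must be positive")
        if self.n_noise < 0:
            raise InputError("n_noise must be >= 0")
        if self.noise_variance <= 0:
            raise InputError("noise_variance must be positive")

    @property
    def predictor_names(self) -> list[str]:
        return ["X"] + [f"Z{i+1}" for i in range(self.n_noise)]

    def true_risk(self, X_genuine: np.ndarray) -> np.ndarray:
        return safe_expit(self.intercept + self.slope * np.asarray(X_genuine))


def generate_population(dgp: DGPSpec, n: int, seed: Optional[int] = None
                        ) -> Tuple[CohortData, np.ndarray]:
    """Simulate a cohort of n individuals from the DGP.

    Returns the cohort and the vector of true risks (known because the
    generating model is known). Fixed seeds give bit-identical cohorts.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(dgp.seed if seed is None else seed)
    x = rng.normal(0.0, np.sqrt(dgp.x_variance), size=n)
    noise = rng.normal(0.0, np.sqrt(dgp.noise_variance),
                       size=(n, dgp.n_noise))
    true_risk = dgp.true_risk(x)
    y = rng.binomial(1, true_risk)
    X = np.column_stack([x, noise]) if dgp.n_noise else x[:, None]
    cohort = CohortData(X=X, y=y, predictor_names=dgp.predictor_names)
    return cohort, true_risk


@dataclass
class TrackedIndividual:
    """A reference individual with an exactly-known true risk.

    Genuine predictor set to logit(P)/slope, all noise coordinates zero, so
    the true model returns risk P to machine precision.
    """

    true_risk: float
    x: np.ndarray
    label: str = ""

    def __post_init__(self):
        if not self.label:
            self.label = f"P={self.true_risk:g}"


def tracked_individuals(P_list: Sequence[float] = DEFAULT_TRACKED_RISKS,
                        dgp: Optional[DGPSpec] = None
                        ) -> list[TrackedIndividual]:
    """Reference individuals at chosen true risks under the DGP."""
    dgp = dgp or DGPSpec()
    if dgp.slope == 0:
        raise InputError("zero slope: no predictor value attains a chosen "
                         "true risk")
    out = []
    for P in P_list:
        if not 0 < P < 1:
            raise InputError(f"true risk must be in (0,1), got {P}")
        xg = (logit(P) - dgp.intercept) / dgp.slope
        x = np.concatenate([[xg], np.zeros(dgp.n_noise)])
        out.append(TrackedIndividual(true_risk=float(P), x=x))
    return out


@dataclass
class SimulationResult:
    """Uncertainty distributions per (development n, tracked individual)."""

    distributions: Dict[Tuple[int, float], RiskDistribution]
    n_list: Sequence[int]
    tracked: Sequence[TrackedIndividual]
    B: int
    n_samples: int
    seed: int
    dgp: DGPSpec
    model_spec: ModelSpec
    redraw_counts: Dict[int, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: n_dev, individual (true risk), sample_index, risk."""
        rows = []
        for (n_dev, P), dist in sorted(self.distributions.items()):
            rows.append(pd.DataFrame({
                "n_dev": n_dev, "true_risk": P,
                "sample_index": np.arange(dist.n_samples),
                "risk": dist.samples,
            }))
        return pd.concat(rows, ignore_index=True)

    def plot_payload(self) -> dict:
        """Prediction clouds vs true risk, one panel per development n."""
        panels = {}
        for n_dev in self.n_list:
            panels[int(n_dev)] = {
                "true_risk": [P for (nd, P) in sorted(self.distributions)
                              if nd == n_dev],
                "samples": [self.distributions[(n_dev, P)].samples.tolist()
                            for (nd, P) in sorted(self.distributions)
                            if nd == n_dev],
            }
        return {"panels": panels, "B": self.B, "n_samples": self.n_samples}


def run_instability_experiment(dgp: Optional[DGPSpec] = None,
                               n_list: Sequence[int] = DEFAULT_N_GRID,
                               B: int = 1000,
                               n_samples: Optional[int] = None,
                               seed: int = 0,
                               model_spec: Optional[ModelSpec] = None,
                               P_list: Sequence[float] = DEFAULT_TRACKED_RISKS
                               ) -> SimulationResult:
    """Run the instability experiment over a grid of development sizes.

    For each n: simulate one development cohort, fit the model (default:
    lasso logistic with cross-validated penalty), build a B-member bootstrap
    ensemble, and record each tracked individual's uncertainty distribution.
    ``n_samples`` defaults to B (each bootstrap member contributes one
    sampled risk); if smaller/larger, samples are drawn with replacement from
    the member predictions.
    """
    if not n_list:
        raise InputError("n_list must be non-empty")
    dgp = dgp or DGPSpec()
    n_samples = B if n_samples is None else int(n_samples)
    tracked = tracked_individuals(P_list, dgp)
    seeds = spawn_seeds(seed, 3 * len(n_list))
    distributions: Dict[Tuple[int, float], RiskDistribution] = {}
    redraw_counts: Dict[int, int] = {}
    spec_used = None
    for i, n_dev in enumerate(n_list):
        cohort_seed, boot_seed, extra_seed = (int(s) for s in seeds[3*i:3*i+3])
        spec = (ModelSpec(penalty="lasso", seed=cohort_seed)
                if model_spec is None
                else ModelSpec(**{**model_spec.to_dict(), "seed": cohort_seed}))
        spec_used = spec
        cohort, _ = generate_population(dgp, int(n_dev), seed=cohort_seed)
        try:
            ensemble = bootstrap_ensemble(cohort, spec, B=B, seed=boot_seed)
        except Exception as e:
            raise type(e)(f"at development size n={n_dev}: {e}") from e
        redraw_counts[int(n_dev)] = ensemble.redraw_count
        resample_rng = np.random.default_rng(extra_seed)
        for ind in tracked:
            dist = sample_bootstrap_distribution(ensemble, ind.x,
                                                 individual_id=ind.label)
            if n_samples != ensemble.B:
                samples = resample_rng.choice(dist.samples, size=n_samples,
                                              replace=True)
                dist = RiskDistribution(samples=samples, source="bootstrap",
                                        individual_id=ind.label)
            distributions[(int(n_dev), ind.true_risk)] = dist
    return SimulationResult(distributions=distributions, n_list=list(n_list),
                            tracked=tracked, B=B, n_samples=n_samples,
                            seed=seed, dgp=dgp, model_spec=spec_used,
                            redraw_counts=redraw_counts)


def run_coverage_experiment(n_replicates: int = 150, n: int = 1000,
                            B: int = 400, level: float = 0.95,
                            seed: int = 0,
                            true_beta: Sequence[float] = (1.0, 1.0),
                            true_intercept: float = 0.0,
                            profile_risks: Sequence[float] = (0.1, 0.3, 0.5,
                                                              0.7, 0.9)
                            ) -> dict:
    """Empirical coverage of percentile bootstrap intervals under a correctly
    specified two-predictor logistic model.

    Each replicate: simulate development data (standard-normal predictors,
    known coefficients), fit unpenalised logistic regression, build a
    B-member bootstrap ensemble, and form equal-tailed percentile intervals
    at ``level`` for fixed covariate profiles whose true risks are
    ``profile_risks`` (profiles solve intercept + beta1 * x1 = logit(P) with
    x2 = 0). Returns the fraction of intervals containing the true risk.
    """
    p = len(true_beta)
    beta = np.asarray(true_beta, dtype=float)
    profiles = []
    for P in profile_risks:
        x = np.zeros(p)
        x[0] = (logit(P) - true_intercept) / beta[0]
        profiles.append(x)
    profiles = np.array(profiles)
    true_risks = safe_expit(true_intercept + profiles @ beta)

    seeds = spawn_seeds(seed, 2 * n_replicates)
    names = [f"x{i+1}" for i in range(p)]
    hits = 0
    total = 0
    alpha = (1.0 - level) / 2.0
    for r in range(n_replicates):
        data_seed, boot_seed = int(seeds[2 * r]), int(seeds[2 * r + 1])
        rng = np.random.default_rng(data_seed)
        X = rng.normal(size=(n, p))
        y = rng.binomial(1, safe_expit(true_intercept + X @ beta))
        cohort = CohortData(X=X, y=y, predictor_names=names)
        spec = ModelSpec(penalty="none", seed=boot_seed)
        ens = bootstrap_ensemble(cohort, spec, B=B, seed=boot_seed)
        preds = ens.predict_members(profiles)  # (n_profiles, B)
        lo, hi = np.quantile(preds, [alpha, 1.0 - alpha], axis=1)
        hits += int(np.sum((lo <= true_risks) & (true_risks <= hi)))
        total += len(true_risks)
    return {"coverage": hits / total, "n_intervals": total, "level": level,
            "n_replicates": n_replicates, "n": n, "B": B}


# Documented fixed coefficients for the low-prevalence cohort emulator.
# Continuous predictors are standard-normal (think standardized age, blood
# pressure, heart rate, weight); binary predictors have stated prevalences
# (think high Killip class, diabetes, previous infarction, anterior site).
GUSTO_LIKE_CONTINUOUS = {
    "age": 0.9, "sysbp": -0.4, "pulse": 0.35, "weight": -0.15,
}
GUSTO_LIKE_BINARY = {
    # name: (prevalence, coefficient)
    "killip_high": (0.15, 0.8),
    "diabetes": (0.15, 0.3),
    "prev_mi": (0.17, 0.4),
    "anterior_mi": (0.39, 0.35),
}


def generate_gusto_like(n: int, prevalence: float = 2851 / 40830,
                        n_predictors: int = 8, seed: int = 0
                        ) -> Tuple[CohortData, np.ndarray]:
    """Synthetic low-prevalence cohort with eight mixed predictors.

    Emulates the *shape* of a large acute-myocardial-infarction trial cohort
    (binary 30-day mortality, prevalence ~0.07, eight predictors); it does
    not reproduce any real dataset. The intercept is solved by bisection on
    the drawn predictor matrix so the cohort's mean true risk equals
    ``prevalence`` to 1e-6; outcomes are then Bernoulli draws from the true
    risks.
    """
    if not 0 < prevalence < 1:
        raise InputError("prevalence must be in (0,1)")
    if n < 1:
        raise InputError("n must be >= 1")
    names_c = list(GUSTO_LIKE_CONTINUOUS)
    names_b = list(GUSTO_LIKE_BINARY)
    if n_predictors != len(names_c) + len(names_b):
        raise InputError(f"this generator defines exactly "
                         f"{len(names_c) + len(names_b)} predictors")
    rng = np.random.default_rng(seed)
    Xc = rng.normal(size=(n, len(names_c)))
    Xb = np.column_stack([
        rng.binomial(1, GUSTO_LIKE_BINARY[name][0], size=n) for name in names_b])
    X = np.column_stack([Xc, Xb]).astype(float)
    beta = np.array([GUSTO_LIKE_CONTINUOUS[c] for c in names_c]
                    + [GUSTO_LIKE_BINARY[b][1] for b in names_b])
    lp_nointercept = X @ beta

    def mean_risk(b0):
        return float(np.mean(safe_expit(b0 + lp_nointercept))) - prevalence

    lo, hi = -40.0, 40.0
    if mean_risk(lo) > 0 or mean_risk(hi) < 0:
        raise InputError(f"prevalence {prevalence} unattainable with the "
                         "fixed coefficient scale")
    b0 = brentq(mean_risk, lo, hi, xtol=1e-9)
    true_risk = safe_expit(b0 + lp_nointercept)
    assert abs(true_risk.mean() - prevalence) < 1e-6
    y = rng.binomial(1, true_risk)
    cohort = CohortData(X=X, y=y, predictor_names=names_c + names_b)
    return cohort, true_risk
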