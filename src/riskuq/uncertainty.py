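"""Per-individual uncertainty distributions and intervals.

Two routes to an individual's uncertainty distribution:

* **Bootstrap**: resample the development cohort with replacement n-out-of-n,
  refit the entire model pipeline (including lasso tuning) on each resample,
  and read off the B predicted risks for the individual. Model-agnostic and
  the default.
* **Parametric**: draw parameter vectors from a multivariate normal centred
  at the estimates with the fitted model's covariance matrix and map each
  through the logistic link — the Laplace (normal) approximation to a
  Bayesian posterior. Available only for unpenalised fits, which carry a
  covariance.

Summaries are equal-tailed percentile intervals plus mean/median/mode point
estimates taken from the distribution itself, so a point estimate can be
"uncertainty aware" rather than the plug-in value from the single fitted
equation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import safe_expit, spawn_seeds, write_json_atomic
from .cohort import CohortData
from .exceptions import DegenerateOutcomeError, InputError, SerializationError
from .logistic import (FittedRiskModel, ModelSpec, fit_model, model_from_record,
                       predict_risk)

ENSEMBLE_FORMAT_VERSION = 1
_REDRAW_CAP = 100


@dataclass
class UncertaintyInterval:
    """Equal-tailed interval for one individual's risk at a nominal level."""

    level: float
    lower: float
    upper: float

    def __post_init__(self):
        if not 0 < self.level < 1:
            raise InputError(f"level must be in (0,1), got {self.level}")
        if not 0 <= self.lower <= self.upper <= 1:
            raise InputError(
                f"need 0 <= lower <= upper <= 1, got [{self.lower}, {self.upper}]")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, p: float) -> bool:
        return self.lower <= p <= self.upper


@dataclass
class RiskDistribution:
    """Sampled risks for one individual, with provenance."""

    samples: np.ndarray
    source: str  # "bootstrap" | "parametric"
    individual_id: Optional[str] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) < 1:
            raise InputError("samples must be a non-empty 1-D vector")
        if self.samples.min() < 0 or self.samples.max() > 1:
            raise InputError("risk samples must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class RiskSummary:
    """Point estimates and intervals read off one uncertainty distribution."""

    mean: float
    median: float
    mode: float
    intervals: Dict[float, UncertaintyInterval]
    plug_in: Optional[float] = None


@dataclass
class BootstrapEnsemble:
    """The original fitted model plus B bootstrap refits of the full pipeline."""

    original: FittedRiskModel
    members: Sequence[FittedRiskModel]
    seed: int
    redraw_count: int = 0
    spec: Optional[ModelSpec] = None

    def __post_init__(self):
        if len(self.members) < 1:
            raise InputError("ensemble needs at least one member")
        names = list(self.original.predictor_names)
        for m in self.members:
            if list(m.predictor_names) != names:
                raise InputError("all members must share the original model's "
                                 "predictor_names")
        if self.spec is None:
            self.spec = self.original.spec

    @property
    def B(self) -> int:
        return len(self.members)

    def coefficient_matrix(self) -> np.ndarray:
        """(B, p+1) matrix of (intercept, coefficients) across members."""
        return np.array([[m.intercept, *m.coefficients] for m in self.members])

    def predict_members(self, X: np.ndarray) -> np.ndarray:
        """(n, B) matrix of member-predicted risks for rows of ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.original.p:
            raise InputError(
                f"predictor matrix has {X.shape[1]} columns, model expects "
                f"{self.original.p}")
        C = self.coefficient_matrix()
        return safe_expit(C[:, 0][None, :] + X @ C[:, 1:].T)


def _resample(data: CohortData, rng: np.random.Generator) -> tuple[CohortData, int]:
    """n-out-of-n resample with replacement; redraw while single-class."""
    redraws = 0
    for _ in range(_REDRAW_CAP + 1):
        idx = rng.integers(0, data.n, size=data.n)
        y = data.y[idx]
        if 0 < y.sum() < data.n:
            boot = CohortData(X=data.X[idx], y=y,
                              predictor_names=data.predictor_names,
                              ids=np.asarray(data.ids)[idx])
            return boot, redraws
        redraws += 1
    raise DegenerateOutcomeError(
        f"bootstrap resample still single-class after {_REDRAW_CAP} redraws; "
        "the cohort has too few events to bootstrap")


def bootstrap_ensemble(data: CohortData, spec: ModelSpec, B: int = 1000,
                       seed: int = 0) -> BootstrapEnsemble:
    """Build a bootstrap ensemble by refitting the full pipeline on B
    resamples of the development cohort.

    Each member refit repeats every step of model development, including
    lasso penalty tuning, so the ensemble reflects selection uncertainty.
    Resamples that come out single-class are redrawn (cap 100 per member)
    and the total redraw count recorded. One master seed drives deterministic
    per-member substreams, so the result is reproducible.
    """
    if B < 1:
        raise InputError(f"B must be >= 1, got {B}")
    if data.n_events < 2 or data.n - data.n_events < 2:
        raise DegenerateOutcomeError(
            f"bootstrap needs at least 2 events and 2 non-events; cohort has "
            f"{data.n_events} events in {data.n} rows")
    original = fit_model(data, spec)
    member_seeds = spawn_seeds(seed, B)
    members = []
    total_redraws = 0
    for b in range(B):
        sub = int(member_seeds[b])
        rng = np.random.default_rng(sub)
        boot, redraws = _resample(data, rng)
        total_redraws += redraws
        member_spec = ModelSpec(**{**spec.to_dict(), "seed": sub})
        members.append(fit_model(boot, member_spec))
    return BootstrapEnsemble(original=original, members=members, seed=seed,
                             redraw_count=total_redraws, spec=spec)


def sample_bootstrap_distribution(ensemble: BootstrapEnsemble, x,
                                  individual_id: Optional[str] = None
                                  ) -> RiskDistribution:
    """The individual's bootstrap uncertainty distribution: one predicted
    risk per ensemble member."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InputError("x must be a single predictor vector")
    samples = ensemble.predict_members(x[None, :])[0]
    return RiskDistribution(samples=samples, source="bootstrap",
                            individual_id=individual_id)


def parametric_sample(model: FittedRiskModel, x, S: int = 1000,
                      seed: int = 0, individual_id: Optional[str] = None
                      ) -> RiskDistribution:
    """Normal-approximation (Laplace) uncertainty distribution.

    Draws S parameter vectors from MVN(estimates, varcov) and maps each
    through expit((1, x) . draw). Stands in for a Bayesian posterior under a
    flat prior; only available when the fit carries a covariance matrix
    (i.e. penalty = "none").
    """
    if model.varcov is None:
        raise InputError("no covariance available for penalised fit; "
                         "parametric sampling requires penalty='none'")
    if S < 1:
        raise InputError("S must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.shape != (model.p,):
        raise InputError(f"x must have length {model.p}, got {x.shape}")
    rng = np.random.default_rng(seed)
    mean = np.concatenate([[model.intercept], model.coefficients])
    draws = rng.multivariate_normal(mean, model.varcov, size=S,
                                    method="eigh")
    design = np.concatenate([[1.0], x])
    samples = safe_expit(draws @ design)
    return RiskDistribution(samples=samples, source="parametric",
                            individual_id=individual_id)


def wald_interval(model: FittedRiskModel, x, level: float = 0.95
                  ) -> UncertaintyInterval:
    """Closed-form normal-theory interval on the logit scale.

    expit(lp ± z * se(lp)) with se(lp)^2 = (1,x) varcov (1,x)^T; the
    large-S limit of :func:`parametric_sample` percentile intervals.
    """
    if model.varcov is None:
        raise InputError("no covariance available for penalised fit")
    if not 0 < level < 1:
        raise InputError(f"level must be in (0,1), got {level}")
    x = np.asarray(x, dtype=float)
    if x.shape != (model.p,):
        raise InputError(f"x must have length {model.p}, got {x.shape}")
    design = np.concatenate([[1.0], x])
    lp = float(design @ np.concatenate([[model.intercept], model.coefficients]))
    var = float(design @ model.varcov @ design)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    return UncertaintyInterval(level=level,
                               lower=float(safe_expit(lp - z * se)),
                               upper=float(safe_expit(lp + z * se)))


def _histogram_mode(samples: np.ndarray, mean: float, bins: int = 100) -> float:
    """Midpoint of the fullest bin of a fixed 100-bin histogram over [0,1];
    ties broken toward the bin nearest the mean."""
    counts, edges = np.histogram(samples, bins=bins, range=(0.0, 1.0))
    mids = (edges[:-1] + edges[1:]) / 2
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    pick = tied[np.argmin(np.abs(mids[tied] - mean))]
    return float(mids[pick])


def percentile_interval(samples: np.ndarray, level: float) -> UncertaintyInterval:
    """Equal-tailed percentile interval of sampled risks."""
    if not 0 < level < 1:
        raise InputError(f"level must be in (0,1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return UncertaintyInterval(level=level, lower=float(lo), upper=float(hi))


def summarize(dist: RiskDistribution, levels: Sequence[float] = (0.50, 0.95),
              plug_in: Optional[float] = None) -> RiskSummary:
    """Point estimates (mean, median, mode) and equal-tailed percentile
    intervals of an uncertainty distribution."""
    s = dist.samples
    mean = float(s.mean())
    intervals = {float(lv): percentile_interval(s, lv) for lv in levels}
    return RiskSummary(mean=mean, median=float(np.median(s)),
                       mode=_histogram_mode(s, mean), intervals=intervals,
                       plug_in=plug_in)


def instability_diagnostics(ensemble: BootstrapEnsemble, data: CohortData,
                            threshold: Optional[float] = None,
                            level: float = 0.95) -> dict:
    """Per-individual instability table and plot payloads.

    For every cohort row: the plug-in risk from the original model, the mean
    absolute deviation (MAD) of the bootstrap predictions around it, and a
    percentile interval. When a decision threshold is given, also the
    classification instability index — the fraction of bootstrap predictions
    on the opposite side of the threshold from the plug-in classification
    (ties at the threshold count as "act").

    Returns a dict with a ``table`` DataFrame and payloads for (i) a
    bootstrap-vs-original prediction scatter and (ii) a classification
    instability plot.
    """
    if list(data.predictor_names) != list(ensemble.original.predictor_names):
        raise InputError("cohort predictors do not match the ensemble's model")
    plug_in = predict_risk(ensemble.original, data.X)
    P = ensemble.predict_members(data.X)  # (n, B)
    mad = np.mean(np.abs(P - plug_in[:, None]), axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(P, [alpha, 1 - alpha], axis=1)
    table = pd.DataFrame({
        "id": np.asarray(data.ids),
        "plug_in": plug_in,
        "mad": mad,
        "lower": lo,
        "upper": hi,
    })
    payload = {
        "scatter": {"plug_in": plug_in, "bootstrap": P, "level": level},
    }
    if threshold is not None:
        decide_act = plug_in >= threshold
        opposite = np.where(decide_act[:, None], P < threshold, P >= threshold)
        table["instability_index"] = opposite.mean(axis=1)
        payload["classification_instability"] = {
            "plug_in": plug_in,
            "instability_index": table["instability_index"].to_numpy(),
            "threshold": threshold,
        }
    payload["table"] = table
    return payload


def _model_record(m: FittedRiskModel) -> dict:
    return {
        "spec": m.spec.to_dict(),
        "intercept": m.intercept,
        "coefficients": m.coefficients,
        "predictor_names": list(m.predictor_names),
        "n_dev": m.n_dev,
        "events_dev": m.events_dev,
        "varcov": m.varcov,
        "chosen_lambda": m.chosen_lambda,
    }


def export_ensemble(ensemble: BootstrapEnsemble, path) -> None:
    """Write the ensemble (original + all members) as versioned JSON.

    This is the portable artefact that lets a model's uncertainty travel
    with it to evaluation settings: coefficients round-trip bit-exactly via
    full-precision decimal repr.
    """
    obj = {
        "format_version": ENSEMBLE_FORMAT_VERSION,
        "kind": "riskuq-ensemble",
        "B": ensemble.B,
        "seed": ensemble.seed,
        "redraw_count": ensemble.redraw_count,
        "spec": ensemble.spec.to_dict(),
        "original": _model_record(ensemble.original),
        "members": [_model_record(m) for m in ensemble.members],
    }
    write_json_atomic(path, obj)


def import_ensemble(path) -> BootstrapEnsemble:
    """Read an ensemble written by :func:`export_ensemble`."""
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except (OSError, json.JSONDecodeError) as e:
        raise SerializationError(f"unreadable ensemble file {path}: {e}") from e
    version = obj.get("format_version")
    if version != ENSEMBLE_FORMAT_VERSION:
        raise SerializationError(
            f"unknown format_version {version!r} in {path} "
            f"(expected {ENSEMBLE_FORMAT_VERSION})")
    try:
        members = [model_from_record(r) for r in obj["members"]]
        if len(members) != obj["B"]:
            raise SerializationError(
                f"truncated ensemble file {path}: B={obj['B']} but "
                f"{len(members)} members present")
        return BootstrapEnsemble(
            original=model_from_record(obj["original"]),
            members=members, seed=int(obj["seed"]),
            redraw_count=int(obj["redraw_count"]),
            spec=ModelSpec.from_dict(obj["spec"]))
    except (KeyError, TypeError) as e:
        raise SerializationError(
            f"truncated or malformed ensemble file {path}: {e}") from e


def distribution_frame(dists: Sequence[RiskDistribution]) -> pd.DataFrame:
    """Tidy export: one row per (individual, sample)."""
    frames = []
    for d in dists:
        frames.append(pd.DataFrame({
            "individual_id": d.individual_id,
            "sample_index": np.arange(d.n_samples),
            "risk": d.samples,
        }))
    return pd.concat(frames, ignore_index=True)
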