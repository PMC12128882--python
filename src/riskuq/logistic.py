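"""Fitting and prediction for unpenalised and lasso logistic risk models.

The unpenalised path delegates to statsmodels (Newton/IRLS) and keeps the
variance-covariance matrix of the parameter estimates — the inverse observed
information — which downstream code uses for parametric (normal
approximation) uncertainty. The lasso path tunes the penalty by K-fold
cross-validated binomial deviance over a logarithmic grid; no covariance is
reported for penalised fits because post-selection covariances are not well
defined.

Predictors are standardized internally for penalised fits and coefficients
are reported back on the original scale, so a fitted model is always
"intercept + x . coefficients" in the units the cohort was supplied in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold

from ._lasso import lambda_grid, lasso_logistic, lasso_path
from ._utils import safe_expit, write_json_atomic
from .cohort import CohortData
from .exceptions import (ConvergenceError, DegenerateOutcomeError, InputError,
                         SerializationError)

MODEL_FORMAT_VERSION = 1

# |coefficient| on the standardized scale beyond which an unpenalised fit is
# treated as (quasi-)separated rather than estimable.
_SEPARATION_BOUND = 30.0


@dataclass
class ModelSpec:
    """Specification of a logistic risk model fit.

    Parameters
    ----------
    penalty : {"none", "lasso"}
        "none" gives maximum likelihood with a parameter covariance matrix;
        "lasso" gives an L1-penalised fit tuned by cross-validation.
    seed : int
        Mandatory; controls cross-validation fold assignment (the only
        stochastic step in fitting).
    cv_folds, n_lambdas, lambda_min_ratio
        Lasso tuning: K-fold CV minimising binomial deviance over
        ``n_lambdas`` log-spaced penalties from lambda_max down to
        ``lambda_max * lambda_min_ratio``.
    fixed_lambda : float, optional
        Skip tuning and fit at this penalty (standardized scale).
    standardize : bool
        Standardize predictors internally for penalised fits (coefficients
        are always reported on the original scale).
    """

    penalty: str = "none"
    seed: int = 0
    family: str = "logistic"
    cv_folds: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    fixed_lambda: Optional[float] = None
    standardize: bool = True

    def __post_init__(self):
        if self.family != "logistic":
            raise InputError(f"unsupported family {self.family!r}")
        if self.penalty not in ("none", "lasso"):
            raise InputError(f"unsupported penalty {self.penalty!r}")
        if self.seed is None:
            raise InputError("a seed is mandatory (cross-validation folds are "
                             "stochastic)")
        self.seed = int(self.seed)
        if self.penalty == "lasso":
            if self.cv_folds < 2:
                raise InputError("cv_folds must be >= 2 for lasso tuning")
            if self.n_lambdas < 1:
                raise InputError("n_lambdas must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass
class FittedRiskModel:
    """A fitted logistic risk model: log-odds intercept plus one coefficient
    per predictor, on the original predictor scale.

    ``varcov`` is the (p+1)x(p+1) covariance of (intercept, coefficients),
    present only for unpenalised fits. ``chosen_lambda`` records the tuned
    penalty for lasso fits.
    """

    intercept: float
    coefficients: np.ndarray
    predictor_names: Sequence[str]
    spec: ModelSpec
    n_dev: int
    events_dev: int
    varcov: Optional[np.ndarray] = None
    chosen_lambda: Optional[float] = field(default=None, compare=False)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.predictor_names):
            raise InputError("coefficients length must match predictor_names")
        if self.varcov is not None:
            self.varcov = np.asarray(self.varcov, dtype=float)
            k = len(self.coefficients) + 1
            if self.varcov.shape != (k, k):
                raise InputError(f"varcov must be {k}x{k}")
            if not np.allclose(self.varcov, self.varcov.T, atol=1e-8):
                raise InputError("varcov must be symmetric")
            evals = np.linalg.eigvalsh((self.varcov + self.varcov.T) / 2)
            if evals.min() < -1e-8 * max(1.0, evals.max()):
                raise InputError("varcov must be positive semi-definite")

    @property
    def p(self) -> int:
        return len(self.coefficients)

    def linear_predictor(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.p:
            raise InputError(
                f"predictor vector has length {x.shape[-1]}, model expects {self.p}")
        return self.intercept + x @ self.coefficients

    def predict_risk(self, x):
        return predict_risk(self, x)


def predict_risk(model: FittedRiskModel, x):
    """Plug-in risk: expit(intercept + x . coefficients), strictly in (0, 1).

    ``x`` may be one predictor vector (returns a scalar) or an (n, p) matrix
    (returns a vector).
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    out = safe_expit(model.linear_predictor(x))
    return float(out) if scalar else out


def _check_fittable(data: CohortData) -> None:
    events = data.n_events
    if events == 0 or events == data.n:
        raise DegenerateOutcomeError(
            f"degenerate outcome: {events} events in {data.n} rows "
            "(need at least one event and one non-event)")


def _fit_unpenalised(data: CohortData, spec: ModelSpec) -> FittedRiskModel:
    Xc = np.column_stack([np.ones(data.n), data.X])
    model = sm.Logit(data.y, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, method="newton", maxiter=100)
        except Exception as e:  # statsmodels raises on hard separation
            raise ConvergenceError(
                f"logistic fit failed, consistent with perfect separation: {e}"
            ) from e
    params = np.asarray(res.params)
    sds = np.concatenate([[1.0], data.X.std(axis=0)])
    sds[sds == 0] = 1.0
    if (not res.mle_retvals.get("converged", True)
            or np.max(np.abs(params * sds)) > _SEPARATION_BOUND):
        raise ConvergenceError(
            "perfect separation detected: maximum-likelihood coefficients "
            "diverge; an unpenalised logistic model is not estimable")
    varcov = np.asarray(res.cov_params())
    return FittedRiskModel(intercept=float(params[0]), coefficients=params[1:],
                           predictor_names=list(data.predictor_names),
                           spec=spec, n_dev=data.n, events_dev=data.n_events,
                           varcov=varcov)


def _cv_deviance(Xs, y, lams, folds, seed, thresh) -> np.ndarray:
    """Summed held-out binomial deviance per penalty over stratified folds."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros(len(lams))
    for train, test in skf.split(Xs, y):
        b0s, betas = lasso_path(Xs[train], y[train], lams, thresh=thresh)
        pr = safe_expit(b0s[None, :] + Xs[test] @ betas.T)
        yt = y[test, None]
        dev += -2.0 * np.sum(yt * np.log(pr) + (1 - yt) * np.log1p(-pr), axis=0)
    return dev


def _fit_lasso(data: CohortData, spec: ModelSpec) -> FittedRiskModel:
    if spec.standardize:
        mu = data.X.mean(axis=0)
        sd = data.X.std(axis=0)
    else:
        mu = np.zeros(data.p)
        sd = np.ones(data.p)
    constant = sd == 0
    sd = np.where(constant, 1.0, sd)
    Xs = (data.X - mu) / sd

    y = data.y.astype(float)
    if spec.fixed_lambda is not None:
        lam = float(spec.fixed_lambda)
    else:
        lams = lambda_grid(Xs, y, spec.n_lambdas, spec.lambda_min_ratio)
        dev = _cv_deviance(Xs, y, lams, spec.cv_folds, spec.seed, thresh=1e-7)
        lam = float(lams[int(np.argmin(dev))])
    b0, beta_s = lasso_logistic(Xs, y, lam, thresh=1e-9)
    beta_s = np.where(constant, 0.0, beta_s)
    # back-transform to the original predictor scale
    beta = beta_s / sd
    intercept = b0 - float(beta @ mu)
    return FittedRiskModel(intercept=intercept, coefficients=beta,
                           predictor_names=list(data.predictor_names),
                           spec=spec, n_dev=data.n, events_dev=data.n_events,
                           varcov=None, chosen_lambda=lam)


def fit_model(data: CohortData, spec: ModelSpec) -> FittedRiskModel:
    """Fit a logistic risk model to a development cohort.

    Unpenalised fits carry the parameter covariance (inverse observed
    information); lasso fits tune the penalty by cross-validated deviance
    and carry no covariance. Refitting with the same data and spec is
    bit-reproducible.
    """
    _check_fittable(data)
    if spec.penalty == "none":
        return _fit_unpenalised(data, spec)
    return _fit_lasso(data, spec)


def save_model(model: FittedRiskModel, path) -> None:
    """Write a fitted model as versioned JSON."""
    obj = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": "riskuq-model",
        "spec": model.spec.to_dict(),
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "predictor_names": list(model.predictor_names),
        "n_dev": model.n_dev,
        "events_dev": model.events_dev,
        "varcov": model.varcov,
        "chosen_lambda": model.chosen_lambda,
    }
    write_json_atomic(path, obj)


def model_from_record(obj: dict) -> FittedRiskModel:
    varcov = obj.get("varcov")
    return FittedRiskModel(
        intercept=float(obj["intercept"]),
        coefficients=np.asarray(obj["coefficients"], dtype=float),
        predictor_names=list(obj["predictor_names"]),
        spec=ModelSpec.from_dict(obj["spec"]),
        n_dev=int(obj["n_dev"]),
        events_dev=int(obj["events_dev"]),
        varcov=None if varcov is None else np.asarray(varcov, dtype=float),
        chosen_lambda=obj.get("chosen_lambda"),
    )


def load_model(path) -> FittedRiskModel:
    """Read a fitted model written by :func:`save_model`."""
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except (OSError, json.JSONDecodeError) as e:
        raise SerializationError(f"unreadable model file {path}: {e}") from e
    version = obj.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise SerializationError(
            f"unknown format_version {version!r} in {path} "
            f"(expected {MODEL_FORMAT_VERSION})")
    try:
        return model_from_record(obj)
    except (KeyError, TypeError) as e:
        raise SerializationError(f"truncated or malformed model file {path}: {e}"
                                 ) from e
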