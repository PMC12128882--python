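"""Smoothed calibration curves with pointwise confidence bands.

At model evaluation, the uncertainty carried forward from development is
usually unavailable; what an evaluation cohort supports is uncertainty
*conditional on estimated risk*: a smoothed calibration curve (observed risk
as a flexible function of model-estimated risk) with a pointwise confidence
band. The band at a given estimated risk is the uncertainty interval for the
true risk of the group of individuals sharing that estimated risk, and can
be rendered as a frequency statement ("of 100 individuals like you, between
a and b ...").

Default smoother: logistic regression of the outcome on a restricted cubic
spline of logit(estimated risk) — flexible, monotone-friendly, and with
normal-theory bands on the linear predictor that map through expit so curve
and band stay inside [0, 1] by construction. A loess-type alternative with
bootstrap bands is provided for sensitivity analysis.

Subgroup curves (by ethnicity, sex, ...) support fairness checks: a group
with systematically wider bands gets systematically less reliable risk
statements from the model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._utils import safe_expit, logit, write_json_atomic
from .exceptions import DegenerateOutcomeError, ExtrapolationError, InputError

logger = logging.getLogger(__name__)

RISK_CLIP = 1e-6          # estimated risks clipped to [RISK_CLIP, 1-RISK_CLIP]
MIN_EVAL_N = 20           # smallest evaluation set we will smooth
PAYLOAD_FORMAT_VERSION = 1
_HIST_BINS = 50


@dataclass
class EvaluationSet:
    """Estimated risks from the model under evaluation, observed outcomes,
    and optional subgroup labels.

    Estimated risks are clipped to [1e-6, 1 - 1e-6] before any logit
    transform; the clip count is logged and recorded.
    """

    estimated_risks: np.ndarray
    outcomes: np.ndarray
    subgroup: Optional[np.ndarray] = None
    n_clipped: int = field(default=0, compare=False)

    def __post_init__(self):
        p = np.asarray(self.estimated_risks, dtype=float)
        y = np.asarray(self.outcomes)
        if p.ndim != 1 or len(p) != len(y):
            raise InputError("estimated_risks and outcomes must be equal-length "
                             "1-D vectors")
        if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
            raise InputError("estimated risks must lie in [0, 1]")
        if not np.all(np.isin(y, (0, 1))):
            raise InputError("outcomes must be binary 0/1")
        clipped = (p < RISK_CLIP) | (p > 1 - RISK_CLIP)
        self.n_clipped = int(clipped.sum())
        if self.n_clipped:
            logger.warning("clipped %d estimated risks into [%g, %g]",
                           self.n_clipped, RISK_CLIP, 1 - RISK_CLIP)
        self.estimated_risks = np.clip(p, RISK_CLIP, 1 - RISK_CLIP)
        self.outcomes = y.astype(np.int64)
        if self.subgroup is not None:
            self.subgroup = np.asarray(self.subgroup)
            if len(self.subgroup) != len(p):
                raise InputError("subgroup length mismatch")

    @property
    def n(self) -> int:
        return len(self.outcomes)

    @property
    def events(self) -> int:
        return int(self.outcomes.sum())


def load_evaluation(path, risk_column: str = "estimated_risk",
                    outcome_column: str = "outcome",
                    subgroup_column: Optional[str] = None) -> EvaluationSet:
    """Read an evaluation CSV with estimated-risk and outcome columns."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty evaluation file: {path}") from None
    for col in (risk_column, outcome_column):
        if col not in df.columns:
            raise InputError(f"column {col!r} not found in {path}")
    sub = None
    if subgroup_column is not None:
        if subgroup_column not in df.columns:
            raise InputError(f"subgroup column {subgroup_column!r} not found")
        sub = df[subgroup_column].astype(str).to_numpy()
    return EvaluationSet(estimated_risks=df[risk_column].to_numpy(dtype=float),
                         outcomes=df[outcome_column].to_numpy(),
                         subgroup=sub)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis in Harrell's parameterisation.

    With k knots this returns k-1 columns: the linear term plus k-2 truncated
    cubic terms that are linear beyond the boundary knots. Normalised by the
    squared knot range so coefficients stay on comparable scales.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        raise InputError("restricted cubic spline needs >= 3 knots")
    tk, tk1 = knots[-1], knots[-2]
    norm = (knots[-1] - knots[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (np.clip(x - tj, 0, None) ** 3
                - np.clip(x - tk1, 0, None) ** 3 * (tk - tj) / (tk - tk1)
                + np.clip(x - tk, 0, None) ** 3 * (tk1 - tj) / (tk - tk1))
        cols.append(term / norm)
    return np.column_stack(cols)


@dataclass
class CalibrationCurve:
    """Smoothed observed-risk-vs-estimated-risk curve with a pointwise band."""

    grid: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    smoother_meta: dict
    n: int
    events: int
    range_observed: tuple[float, float]

    def __post_init__(self):
        for name in ("grid", "fitted", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (np.all(self.lower <= self.fitted + 1e-12)
                and np.all(self.fitted <= self.upper + 1e-12)):
            raise InputError("need lower <= fitted <= upper pointwise")
        lo, hi = self.range_observed
        if self.grid.min() < lo - 1e-12 or self.grid.max() > hi + 1e-12:
            raise InputError("grid extends beyond the observed risk range")

    @property
    def band_width(self) -> np.ndarray:
        return self.upper - self.lower

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid, "fitted": self.fitted,
                             "lower": self.lower, "upper": self.upper})


def _check_smoothable(ev: EvaluationSet) -> None:
    if ev.n < MIN_EVAL_N:
        raise InputError(
            f"evaluation set has n={ev.n}; smoothing requires n >= {MIN_EVAL_N}")
    if ev.events == 0 or ev.events == ev.n:
        raise DegenerateOutcomeError(
            f"single-class outcomes ({ev.events} events in {ev.n}); "
            "cannot estimate a calibration curve")
    if np.ptp(ev.estimated_risks) < 1e-12:
        raise InputError("no spread in predictions: estimated risks are "
                         "constant, a calibration curve is undefined")


def _rcs_curve(ev: EvaluationSet, level: float, n_knots: int,
               grid_size: int) -> CalibrationCurve:
    lp_obs = logit(ev.estimated_risks)
    qs = {3: (0.10, 0.50, 0.90),
          4: (0.05, 0.35, 0.65, 0.95),
          5: (0.05, 0.275, 0.50, 0.725, 0.95),
          6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
          7: (0.025, 0.18, 0.34, 0.50, 0.66, 0.82, 0.975)}
    if n_knots not in qs:
        raise InputError(f"n_knots must be one of {sorted(qs)}, got {n_knots}")
    knots = np.quantile(lp_obs, qs[n_knots])
    if len(np.unique(knots)) < 3:
        raise InputError("no spread in predictions: spline knots coincide")
    basis = sm.add_constant(rcs_basis(lp_obs, knots), has_constant="add")
    res = sm.GLM(ev.outcomes, basis, family=sm.families.Binomial()).fit()

    lo_obs, hi_obs = float(ev.estimated_risks.min()), float(ev.estimated_risks.max())
    grid = np.linspace(lo_obs, hi_obs, grid_size)
    gb = sm.add_constant(rcs_basis(logit(grid), knots), has_constant="add")
    lp = gb @ res.params
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", gb,
                                      np.asarray(res.cov_params()), gb), 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    return CalibrationCurve(
        grid=grid, fitted=safe_expit(lp),
        lower=safe_expit(lp - z * se), upper=safe_expit(lp + z * se),
        level=level,
        smoother_meta={"method": "rcs-logistic", "n_knots": n_knots,
                       "knots_logit": knots.tolist()},
        n=ev.n, events=ev.events, range_observed=(lo_obs, hi_obs))


def _loess_curve(ev: EvaluationSet, level: float, frac: float,
                 grid_size: int, n_boot: int, seed: int) -> CalibrationCurve:
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = ev.estimated_risks
    lo_obs, hi_obs = float(x.min()), float(x.max())
    grid = np.linspace(lo_obs, hi_obs, grid_size)

    def smooth(xv, yv):
        out = lowess(yv, xv, frac=frac, it=0, xvals=grid)
        return np.clip(out, 0.0, 1.0)

    fitted = smooth(x, ev.outcomes.astype(float))
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, grid_size))
    for b in range(n_boot):
        idx = rng.integers(0, ev.n, ev.n)
        boots[b] = smooth(x[idx], ev.outcomes[idx].astype(float))
    alpha = (1 - level) / 2
    lower, upper = np.quantile(boots, [alpha, 1 - alpha], axis=0)
    return CalibrationCurve(
        grid=grid, fitted=fitted,
        lower=np.minimum(lower, fitted), upper=np.maximum(upper, fitted),
        level=level,
        smoother_meta={"method": "loess-bootstrap", "frac": frac,
                       "n_boot": n_boot, "seed": seed},
        n=ev.n, events=ev.events, range_observed=(lo_obs, hi_obs))


def smooth_calibration(ev: EvaluationSet, smoother: str = "rcs",
                       level: float = 0.95, n_knots: int = 4,
                       grid_size: int = 100, loess_frac: float = 0.6,
                       loess_boot: int = 200, seed: int = 0
                       ) -> CalibrationCurve:
    """Fit a smoothed calibration curve with a pointwise confidence band.

    ``smoother="rcs"`` (default): logistic regression of outcomes on a
    restricted cubic spline (default 4 knots at quantiles
    0.05/0.35/0.65/0.95) of logit(estimated risk), with normal-theory bands
    on the linear predictor. ``smoother="loess"``: local regression with
    percentile-bootstrap bands.
    """
    if not 0 < level < 1:
        raise InputError(f"level must be in (0,1), got {level}")
    _check_smoothable(ev)
    if smoother == "rcs":
        return _rcs_curve(ev, level, n_knots, grid_size)
    if smoother == "loess":
        return _loess_curve(ev, level, loess_frac, grid_size, loess_boot, seed)
    raise InputError(f"unknown smoother {smoother!r} (use 'rcs' or 'loess')")


def _interp_logit(grid, values, p_est):
    """Linear interpolation on the logit scale, safe at band values of 0/1."""
    v = np.clip(values, RISK_CLIP, 1 - RISK_CLIP)
    return float(safe_expit(np.interp(logit(p_est), logit(np.clip(
        grid, RISK_CLIP, 1 - RISK_CLIP)), logit(v))))


def curve_interval_at(curve: CalibrationCurve, p_est: float
                      ) -> UncertaintyIntervalAt:
    """Fitted value and pointwise band at one estimated risk.

    Queries outside the observed estimated-risk range are refused: the curve
    is not extrapolated into regions with no evaluation data.
    """
    lo, hi = curve.range_observed
    if not lo <= p_est <= hi:
        raise ExtrapolationError(
            f"extrapolation refused: estimated risk {p_est:g} outside the "
            f"observed range [{lo:.6g}, {hi:.6g}]")
    exact = np.isclose(curve.grid, p_est, rtol=0, atol=1e-12)
    if exact.any():
        i = int(np.argmax(exact))
        return UncertaintyIntervalAt(level=curve.level, p_est=p_est,
                                     fitted=float(curve.fitted[i]),
                                     lower=float(curve.lower[i]),
                                     upper=float(curve.upper[i]))
    return UncertaintyIntervalAt(
        level=curve.level, p_est=p_est,
        fitted=_interp_logit(curve.grid, curve.fitted, p_est),
        lower=_interp_logit(curve.grid, curve.lower, p_est),
        upper=_interp_logit(curve.grid, curve.upper, p_est))


@dataclass
class UncertaintyIntervalAt:
    """Pointwise curve value and band at one queried estimated risk."""

    level: float
    p_est: float
    fitted: float
    lower: float
    upper: float


def group_statement(curve: CalibrationCurve, p_est: float,
                    group_size: int = 100, outcome_label: str = "have the outcome"
                    ) -> str:
    """Frequency-format statement for the group sharing an estimated risk:
    'In a group of 100 individuals with the same estimated risk as you, the
    model suggests that between about 78 and 100 will ...'."""
    iv = curve_interval_at(curve, p_est)
    lo = round(iv.lower * group_size)
    hi = round(iv.upper * group_size)
    prefix = (f"In a group of {group_size} individuals with the same "
              f"estimated risk as you, the model suggests that ")
    if lo == hi:
        return prefix + f"about {lo} will {outcome_label}."
    return prefix + f"between about {lo} and {hi} will {outcome_label}."


@dataclass
class SubgroupCalibration:
    """Per-subgroup curves plus a band-width comparison on a common grid."""

    curves: Dict[str, CalibrationCurve]
    width_summary: pd.DataFrame     # subgroup, n, events, mean_band_width
    skipped: Dict[str, str]         # subgroup -> reason
    common_grid: np.ndarray


def subgroup_calibration(ev: EvaluationSet, level: float = 0.95,
                         smoother: str = "rcs", **kwargs
                         ) -> SubgroupCalibration:
    """Calibration curves per subgroup with mean pointwise band widths on a
    common grid, for fairness comparison. Groups failing the smoothing
    preconditions are reported in ``skipped``, never silently dropped.
    """
    if ev.subgroup is None:
        raise InputError("evaluation set has no subgroup labels")
    curves: Dict[str, CalibrationCurve] = {}
    skipped: Dict[str, str] = {}
    for g in sorted(set(ev.subgroup.tolist())):
        mask = ev.subgroup == g
        sub = EvaluationSet(estimated_risks=ev.estimated_risks[mask],
                            outcomes=ev.outcomes[mask])
        try:
            curves[g] = smooth_calibration(sub, smoother=smoother,
                                           level=level, **kwargs)
        except (InputError, DegenerateOutcomeError) as e:
            skipped[g] = str(e)
    if curves:
        lo = max(c.range_observed[0] for c in curves.values())
        hi = min(c.range_observed[1] for c in curves.values())
        if hi <= lo:
            common = np.array([])
        else:
            common = np.linspace(lo, hi, 50)
    else:
        common = np.array([])
    rows = []
    for g, c in curves.items():
        if len(common):
            widths = [curve_interval_at(c, p).upper - curve_interval_at(c, p).lower
                      for p in common]
            mean_w = float(np.mean(widths))
        else:
            mean_w = float("nan")
        rows.append({"subgroup": g, "n": c.n, "events": c.events,
                     "mean_band_width": mean_w})
    return SubgroupCalibration(curves=curves,
                               width_summary=pd.DataFrame(rows),
                               skipped=skipped, common_grid=common)


def calibration_plot_payload(curve: CalibrationCurve, ev: EvaluationSet) -> dict:
    """Everything needed to draw a calibration plot: diagonal reference,
    curve + band, and histograms of estimated risks split by outcome
    (50 equal bins on [0, 1])."""
    edges = np.linspace(0.0, 1.0, _HIST_BINS + 1)
    h1, _ = np.histogram(ev.estimated_risks[ev.outcomes == 1], bins=edges)
    h0, _ = np.histogram(ev.estimated_risks[ev.outcomes == 0], bins=edges)
    return {
        "format_version": PAYLOAD_FORMAT_VERSION,
        "diagonal": {"x": [0.0, 1.0], "y": [0.0, 1.0]},
        "curve": {"grid": curve.grid.tolist(),
                  "fitted": curve.fitted.tolist(),
                  "lower": curve.lower.tolist(),
                  "upper": curve.upper.tolist(),
                  "level": curve.level},
        "histograms": {"bin_edges": edges.tolist(),
                       "events": h1.tolist(),
                       "non_events": h0.tolist()},
        "n": curve.n, "events": curve.events,
        "smoother_meta": curve.smoother_meta,
    }


def payload_to_json(payload: dict, path) -> None:
    write_json_atomic(path, payload)


def payload_from_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def plot_calibration(curve: CalibrationCurve, ev: EvaluationSet, path=None):
    """Render the calibration plot (curve, band, diagonal, outcome
    histograms) with matplotlib; returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    payload = calibration_plot_payload(curve, ev)
    fig, (ax, axh) = plt.subplots(
        2, 1, figsize=(6, 7), sharex=True,
        gridspec_kw={"height_ratios": [4, 1], "hspace": 0.08})
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=1, label="perfect calibration")
    ax.plot(curve.grid, curve.fitted, c="C0", label="smoothed curve")
    ax.fill_between(curve.grid, curve.lower, curve.upper, color="C0", alpha=0.25,
                    label=f"{curve.level:.0%} pointwise CI")
    ax.set_ylabel("observed risk")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    edges = np.asarray(payload["histograms"]["bin_edges"])
    mids = (edges[:-1] + edges[1:]) / 2
    w = edges[1] - edges[0]
    axh.bar(mids, payload["histograms"]["non_events"], width=w, alpha=0.6,
            label="no outcome")
    axh.bar(mids, payload["histograms"]["events"], width=w, alpha=0.6,
            label="outcome")
    axh.set_xlabel("estimated risk")
    axh.set_ylabel("count")
    axh.legend(fontsize=7)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
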