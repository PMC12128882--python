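"""Decision analysis under risk-estimate uncertainty.

A binary act / no-act decision (e.g. biopsy / no biopsy) at risk threshold t
is formalised with a four-outcome utility table (true/false positives and
negatives). Writing B = u_tp - u_fn for the net benefit of acting on a case
and H = u_tn - u_fp for the net harm of acting on a non-case, the expected
utility difference of acting at risk p is

    dU(p) = p * B - (1 - p) * H,

which is linear in p and crosses zero exactly at the implied threshold
t = H / (H + B). By linearity, the expected utility over an uncertainty
distribution equals dU(mean risk), so the uncertainty-aware decision is
"act" iff the mean of the distribution is at or above the threshold — which
can differ from the plug-in decision for individuals near the threshold with
skewed distributions.

Beyond the decision itself, the module reports how conclusive it is: the
fraction of the uncertainty distribution on either side of the threshold,
and the classification instability index (mass on the opposite side of the
decision actually taken).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .uncertainty import RiskDistribution, UncertaintyInterval, summarize


def implied_threshold(u_tp: float, u_fp: float, u_fn: float, u_tn: float) -> float:
    """Risk threshold at which acting and not acting have equal expected
    utility: H / (H + B) with B = u_tp - u_fn, H = u_tn - u_fp."""
    B = u_tp - u_fn
    H = u_tn - u_fp
    if B <= 0:
        raise InputError("treatment never beneficial: requires u_tp > u_fn")
    if H < 0:
        raise InputError("negative harm (u_tn < u_fp) would make acting "
                         "dominant; not a decision problem")
    return H / (H + B)


@dataclass(frozen=True)
class UtilitySpec:
    """Utilities of the four classification outcomes.

    ``from_threshold(t)`` builds the normalized net-benefit form
    (u_tp=1, u_fn=0, u_tn=0, u_fp=-t/(1-t)) whose implied threshold is t.
    Absolute utility scales are application-specific configuration.
    """

    u_tp: float
    u_fp: float
    u_fn: float
    u_tn: float

    def __post_init__(self):
        implied_threshold(self.u_tp, self.u_fp, self.u_fn, self.u_tn)  # validates

    @property
    def benefit(self) -> float:
        return self.u_tp - self.u_fn

    @property
    def harm(self) -> float:
        return self.u_tn - self.u_fp

    @property
    def implied_threshold(self) -> float:
        return self.harm / (self.harm + self.benefit)

    @classmethod
    def from_threshold(cls, t: float) -> "UtilitySpec":
        if not 0 <= t < 1:
            raise InputError(f"threshold must be in [0, 1), got {t}")
        return cls(u_tp=1.0, u_fp=-t / (1.0 - t), u_fn=0.0, u_tn=0.0)


def utility_difference(p, u: UtilitySpec):
    """Expected utility of acting minus not acting at risk p:
    dU(p) = p*B - (1-p)*H. Zero exactly at the implied threshold."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InputError("risk p must be in [0, 1]")
    out = p * u.benefit - (1.0 - p) * u.harm
    return float(out) if out.ndim == 0 else out


def expected_utility(dist: RiskDistribution, u: UtilitySpec
                     ) -> tuple[float, str]:
    """Mean utility difference over the uncertainty distribution and the
    decision it implies ("act" iff the mean difference is >= 0).

    By linearity this equals dU(mean risk); the identity is asserted.
    """
    edu = float(np.mean(utility_difference(dist.samples, u)))
    direct = utility_difference(float(dist.samples.mean()), u)
    assert abs(edu - direct) <= 1e-10 * max(1.0, abs(edu))
    # sign(edu) and (mean >= threshold) coincide in exact arithmetic; the
    # explicit comparison keeps ties at the threshold deciding "act" even
    # when edu rounds to a signed zero's worth of noise
    act = float(dist.samples.mean()) >= u.implied_threshold
    return edu, ("act" if act else "no_act")


def threshold_probabilities(dist: RiskDistribution, t: float
                            ) -> tuple[float, float]:
    """(prob_below, prob_above): the fraction of the uncertainty distribution
    on either side of the threshold. Ties at t count as above ("risk >= t
    means act")."""
    if not 0 < t < 1:
        raise InputError(f"threshold must be in (0,1), got {t}")
    above = float(np.mean(dist.samples >= t))
    return 1.0 - above, above


@dataclass
class DecisionSummary:
    """One individual's uncertainty-aware decision at a risk threshold."""

    threshold: float
    point_estimate: float          # mean of the uncertainty distribution
    plug_in: Optional[float]
    decision: str                  # "act" | "no_act"
    prob_above: float
    prob_below: float
    expected_utility_diff: float
    instability_index: float
    conclusive: bool
    interval_overlaps_threshold: Dict[float, bool]
    intervals: Dict[float, UncertaintyInterval]
    individual_id: Optional[str] = None


def classify_with_instability(dist: RiskDistribution, t: float,
                              levels: Sequence[float] = (0.50, 0.95),
                              utilities: Optional[UtilitySpec] = None,
                              plug_in: Optional[float] = None,
                              conclusive_at: float = 0.9) -> DecisionSummary:
    """Decide act/no-act from the distribution mean and quantify instability.

    * decision: mean risk >= t (ties act);
    * instability_index: fraction of samples on the opposite side of t from
      the decision taken;
    * conclusive: majority-side mass >= ``conclusive_at`` (default 0.9 — a
      60/40 split is the canonical inconclusive case);
    * interval_overlaps_threshold: lower < t <= upper per requested level,
      flagging individuals whose interval straddles the threshold.
    """
    if utilities is None:
        utilities = UtilitySpec.from_threshold(t)
    elif abs(utilities.implied_threshold - t) > 1e-9:
        raise InputError(
            f"utilities imply threshold {utilities.implied_threshold:.6g}, "
            f"but t={t} was requested")
    summary = summarize(dist, levels=levels, plug_in=plug_in)
    prob_below, prob_above = threshold_probabilities(dist, t)
    edu, decision = expected_utility(dist, utilities)
    instability = prob_below if decision == "act" else prob_above
    overlaps = {lv: (iv.lower < t <= iv.upper)
                for lv, iv in summary.intervals.items()}
    return DecisionSummary(
        threshold=t, point_estimate=summary.mean, plug_in=plug_in,
        decision=decision, prob_above=prob_above, prob_below=prob_below,
        expected_utility_diff=edu, instability_index=instability,
        conclusive=max(prob_above, prob_below) >= conclusive_at,
        interval_overlaps_threshold=overlaps, intervals=summary.intervals,
        individual_id=dist.individual_id)


def decision_report(dists: Sequence[RiskDistribution], t: float,
                    levels: Sequence[float] = (0.50, 0.95),
                    utilities: Optional[UtilitySpec] = None,
                    plug_ins: Optional[Sequence[float]] = None,
                    conclusive_at: float = 0.9) -> pd.DataFrame:
    """One report row per individual: point estimates, intervals, threshold
    probabilities, expected utility difference, decision, and instability."""
    if plug_ins is None:
        plug_ins = [None] * len(dists)
    rows = []
    for dist, plug in zip(dists, plug_ins):
        s = classify_with_instability(dist, t, levels=levels,
                                      utilities=utilities, plug_in=plug,
                                      conclusive_at=conclusive_at)
        med = float(np.median(dist.samples))
        row = {
            "id": s.individual_id, "plug_in": plug,
            "mean": s.point_estimate, "median": med,
            "prob_above": s.prob_above, "prob_below": s.prob_below,
            "expected_utility_diff": s.expected_utility_diff,
            "decision": s.decision,
            "instability_index": s.instability_index,
            "conclusive": s.conclusive,
        }
        for lv, iv in s.intervals.items():
            pct = f"{lv:g}"
            row[f"lower_{pct}"] = iv.lower
            row[f"upper_{pct}"] = iv.upper
            row[f"overlaps_threshold_{pct}"] = s.interval_overlaps_threshold[lv]
        rows.append(row)
    return pd.DataFrame(rows)
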