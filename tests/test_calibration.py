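import json

import numpy as np
import pytest
from scipy.special import expit, logit

from riskuq import (DegenerateOutcomeError, EvaluationSet, ExtrapolationError,
                    InputError, calibration_plot_payload, curve_interval_at,
                    group_statement, load_evaluation, smooth_calibration,
                    subgroup_calibration)
from riskuq.calibration import payload_from_json, payload_to_json


def calibrated_eval(n, seed=0, transform=None, subgroup=None):
    """Evaluation set with outcomes drawn at (a transform of) the estimated
    risks; transform=None means perfectly calibrated."""
    rng = np.random.default_rng(seed)
    p = rng.beta(2, 2, n)
    true = p if transform is None else transform(p)
    y = rng.binomial(1, true)
    return EvaluationSet(estimated_risks=p, outcomes=y, subgroup=subgroup)


def central_mask(ev, grid):
    lo, hi = np.quantile(ev.estimated_risks, [0.05, 0.95])
    return (grid >= lo) & (grid <= hi)


class TestSmoothCalibration:
    def test_recovers_identity_when_perfectly_calibrated(self):
        ev = calibrated_eval(50000, seed=1)
        c = smooth_calibration(ev)
        m = central_mask(ev, c.grid)
        assert np.max(np.abs(c.fitted[m] - c.grid[m])) < 0.02

    def test_recovers_known_miscalibration(self):
        tf = lambda p: expit(0.5 * logit(p))
        ev = calibrated_eval(50000, seed=2, transform=tf)
        c = smooth_calibration(ev)
        m = central_mask(ev, c.grid)
        assert np.max(np.abs(c.fitted[m] - tf(c.grid[m]))) < 0.03

    def test_duplicating_rows_narrows_bands_not_curve(self):
        ev = calibrated_eval(2000, seed=3)
        c1 = smooth_calibration(ev)
        ev2 = EvaluationSet(
            estimated_risks=np.concatenate([ev.estimated_risks] * 2),
            outcomes=np.concatenate([ev.outcomes] * 2))
        c2 = smooth_calibration(ev2)
        np.testing.assert_allclose(c2.fitted, c1.fitted, atol=1e-9)
        assert np.all(c2.band_width < c1.band_width)

    def test_bands_shrink_like_sqrt_n(self):
        """Quadrupling n roughly halves the mean band width (±25%)."""
        ev1 = calibrated_eval(4000, seed=4)
        ev4 = calibrated_eval(16000, seed=5)
        w1 = smooth_calibration(ev1).band_width.mean()
        w4 = smooth_calibration(ev4).band_width.mean()
        assert w1 / w4 == pytest.approx(2.0, rel=0.25)

    def test_bounds_inside_unit_interval_and_ordered(self):
        ev = calibrated_eval(500, seed=6)
        c = smooth_calibration(ev)
        assert np.all((c.lower >= 0) & (c.upper <= 1))
        assert np.all(c.lower <= c.fitted) and np.all(c.fitted <= c.upper)

    def test_loess_smoother_tracks_identity(self):
        ev = calibrated_eval(8000, seed=7)
        c = smooth_calibration(ev, smoother="loess", loess_boot=50, seed=1)
        m = central_mask(ev, c.grid)
        assert np.max(np.abs(c.fitted[m] - c.grid[m])) < 0.05

    def test_preconditions(self):
        with pytest.raises(InputError, match="n >= 20"):
            smooth_calibration(calibrated_eval(10, seed=8))
        rng = np.random.default_rng(9)
        const = EvaluationSet(estimated_risks=np.full(100, 0.3),
                              outcomes=rng.binomial(1, 0.3, 100))
        with pytest.raises(InputError, match="no spread"):
            smooth_calibration(const)
        oneclass = EvaluationSet(estimated_risks=rng.uniform(size=100),
                                 outcomes=np.zeros(100, dtype=int))
        with pytest.raises(DegenerateOutcomeError):
            smooth_calibration(oneclass)


class TestCurveInterval:
    def test_exact_grid_point_returned_verbatim(self):
        c = smooth_calibration(calibrated_eval(2000, seed=10))
        i = 40
        iv = curve_interval_at(c, float(c.grid[i]))
        assert iv.fitted == c.fitted[i]
        assert iv.lower == c.lower[i]
        assert iv.upper == c.upper[i]

    def test_extrapolation_refused_with_range_in_message(self):
        c = smooth_calibration(calibrated_eval(2000, seed=11))
        with pytest.raises(ExtrapolationError, match="observed range"):
            curve_interval_at(c, 0.9999)

    def test_coverage_of_true_risk_near_nominal(self):
        """Pointwise 95% band at p=0.5 contains the true value 0.5 at about
        the nominal rate over independent perfectly calibrated replicates."""
        hits = 0
        reps = 200
        for r in range(reps):
            c = smooth_calibration(calibrated_eval(1500, seed=1000 + r))
            iv = curve_interval_at(c, 0.5)
            hits += iv.lower <= 0.5 <= iv.upper
        # binomial(200, 0.95) 3.5-sigma band
        assert hits / reps == pytest.approx(0.95, abs=0.06)


class TestGroupStatement:
    def test_paper_style_sentence(self):
        c = smooth_calibration(calibrated_eval(3000, seed=12))
        iv = curve_interval_at(c, 0.5)
        text = group_statement(c, 0.5, group_size=100)
        lo, hi = round(iv.lower * 100), round(iv.upper * 100)
        assert f"between about {lo} and {hi}" in text
        assert "group of 100 individuals" in text

    def test_scaling_to_other_group_sizes(self):
        c = smooth_calibration(calibrated_eval(3000, seed=13))
        iv = curve_interval_at(c, 0.5)
        text = group_statement(c, 0.5, group_size=1000)
        assert f"{round(iv.lower * 1000)}" in text


class TestSubgroups:
    def test_equal_groups_have_similar_widths(self):
        rng = np.random.default_rng(14)
        n = 4000
        sub = np.repeat(["g1", "g2"], n)
        ev = calibrated_eval(2 * n, seed=15, subgroup=sub)
        res = subgroup_calibration(ev)
        w = res.width_summary.set_index("subgroup")["mean_band_width"]
        assert w["g1"] == pytest.approx(w["g2"], rel=0.3)

    def test_smaller_group_has_wider_bands(self):
        rng = np.random.default_rng(16)
        n_big, n_small = 5000, 500
        sub = np.array(["big"] * n_big + ["small"] * n_small)
        ev = calibrated_eval(n_big + n_small, seed=17, subgroup=sub)
        res = subgroup_calibration(ev)
        w = res.width_summary.set_index("subgroup")["mean_band_width"]
        assert w["small"] > w["big"]

    def test_tiny_group_reported_not_dropped(self):
        n = 1000
        sub = np.array(["big"] * n + ["tiny"] * 5)
        ev = calibrated_eval(n + 5, seed=18, subgroup=sub)
        res = subgroup_calibration(ev)
        assert "tiny" in res.skipped
        assert "tiny" not in res.curves
        assert "big" in res.curves


class TestPlotPayload:
    def test_histograms_sum_to_n_and_split_by_outcome(self):
        ev = calibrated_eval(1234, seed=19)
        c = smooth_calibration(ev)
        payload = calibration_plot_payload(c, ev)
        h = payload["histograms"]
        assert sum(h["events"]) + sum(h["non_events"]) == ev.n
        assert sum(h["events"]) == ev.events

    def test_event_histogram_empty_iff_no_events(self):
        rng = np.random.default_rng(20)
        ev = EvaluationSet(estimated_risks=rng.uniform(0.1, 0.9, 50),
                           outcomes=np.zeros(50, dtype=int))
        # payload generation does not require a fittable curve
        c = smooth_calibration(calibrated_eval(500, seed=21))
        payload = calibration_plot_payload(c, ev)
        assert sum(payload["histograms"]["events"]) == 0

    def test_payload_json_roundtrip(self, tmp_path):
        ev = calibrated_eval(300, seed=22)
        c = smooth_calibration(ev)
        payload = calibration_plot_payload(c, ev)
        path = tmp_path / "payload.json"
        payload_to_json(payload, path)
        assert payload_from_json(path) == json.loads(json.dumps(payload))


def test_load_evaluation(tmp_path):
    import pandas as pd
    path = tmp_path / "eval.csv"
    pd.DataFrame({"estimated_risk": [0.1, 0.5, 0.9],
                  "outcome": [0, 1, 1],
                  "subgroup": ["a", "a", "b"]}).to_csv(path, index=False)
    ev = load_evaluation(path, subgroup_column="subgroup")
    assert ev.n == 3 and ev.events == 2
    with pytest.raises(InputError, match="column"):
        load_evaluation(path, risk_column="nope")
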