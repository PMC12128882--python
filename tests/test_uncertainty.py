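import json

import numpy as np
import pytest
from scipy.special import expit, logit

from riskuq import (CohortData, DegenerateOutcomeError, FittedRiskModel,
                    InputError, ModelSpec, RiskDistribution, SerializationError,
                    bootstrap_ensemble, export_ensemble, import_ensemble,
                    instability_diagnostics, parametric_sample,
                    percentile_interval, sample_bootstrap_distribution,
                    summarize, wald_interval)
from riskuq.uncertainty import BootstrapEnsemble


def make_model(intercept=0.0, coefficients=(0.0,), varcov=None, names=None):
    names = names or [f"x{i}" for i in range(len(coefficients))]
    return FittedRiskModel(intercept=intercept,
                           coefficients=np.asarray(coefficients, float),
                           predictor_names=names,
                           spec=ModelSpec(penalty="none", seed=0),
                           n_dev=10, events_dev=5, varcov=varcov)


class TestBootstrapEnsemble:
    def test_fixed_seed_is_deterministic(self, small_cohort):
        spec = ModelSpec(penalty="none", seed=3)
        e1 = bootstrap_ensemble(small_cohort, spec, B=3, seed=12)
        e2 = bootstrap_ensemble(small_cohort, spec, B=3, seed=12)
        for m1, m2 in zip(e1.members, e2.members):
            assert m1.intercept == m2.intercept
            np.testing.assert_array_equal(m1.coefficients, m2.coefficients)

    def test_constant_outcome_rejected(self):
        data = CohortData(X=np.arange(10, dtype=float)[:, None],
                          y=np.ones(10, dtype=int), predictor_names=["x"])
        with pytest.raises(DegenerateOutcomeError):
            bootstrap_ensemble(data, ModelSpec(penalty="none", seed=0),
                               B=2, seed=0)

    def test_b_must_be_positive(self, small_cohort):
        with pytest.raises(InputError, match="B"):
            bootstrap_ensemble(small_cohort, ModelSpec(seed=0), B=0, seed=0)

    def test_null_data_lasso_slopes_mostly_zero(self):
        """Outcome independent of predictors: the lasso shrinks fully in the
        majority of bootstrap refits, so the median slope over members is 0.
        (Holds for a typical null cohort; a cohort with unusually large
        spurious correlation can legitimately retain a predictor.)"""
        rng = np.random.default_rng(1)
        data = CohortData(X=rng.normal(size=(300, 3)),
                          y=rng.binomial(1, 0.5, 300),
                          predictor_names=["a", "b", "c"])
        spec = ModelSpec(penalty="lasso", seed=1, cv_folds=10, n_lambdas=30)
        ens = bootstrap_ensemble(data, spec, B=15, seed=101)
        med = np.median(ens.coefficient_matrix()[:, 1:], axis=0)
        np.testing.assert_array_equal(med, np.zeros(3))


class TestSampling:
    def test_identical_members_give_degenerate_distribution(self):
        m = make_model(intercept=logit(0.3))
        ens = BootstrapEnsemble(original=m, members=[m] * 5, seed=0)
        d = sample_bootstrap_distribution(ens, np.zeros(1))
        assert np.all(d.samples == pytest.approx(0.3, abs=1e-12))
        s = summarize(d)
        assert s.intervals[0.95].width == pytest.approx(0.0, abs=1e-12)

    def test_interval_narrows_with_development_n(self):
        """95% interval for a mid-risk individual is strictly narrower when
        the development cohort grows from n=50 to n=5000."""
        from riskuq import DGPSpec, generate_population
        dgp = DGPSpec(n_noise=0)
        widths = {}
        for n in (50, 5000):
            cohort, _ = generate_population(dgp, n, seed=31)
            ens = bootstrap_ensemble(cohort, ModelSpec(penalty="none", seed=1),
                                     B=150, seed=17)
            d = sample_bootstrap_distribution(ens, np.zeros(1))
            widths[n] = percentile_interval(d.samples, 0.95).width
        assert widths[5000] < widths[50]

    def test_dimension_mismatch(self, small_cohort):
        ens = bootstrap_ensemble(small_cohort, ModelSpec(penalty="none", seed=0),
                                 B=2, seed=0)
        with pytest.raises(InputError):
            sample_bootstrap_distribution(ens, np.zeros(7))


class TestParametric:
    def test_zero_varcov_returns_plug_in(self):
        m = make_model(intercept=logit(0.2), varcov=np.zeros((2, 2)))
        d = parametric_sample(m, np.zeros(1), S=50, seed=0)
        assert np.all(d.samples == pytest.approx(0.2, abs=1e-12))

    def test_monte_carlo_matches_closed_form_mean(self):
        """Intercept-only N(0,1) posterior: mean of logit(samples) is 0."""
        m = FittedRiskModel(intercept=0.0, coefficients=np.zeros(0),
                            predictor_names=[], spec=ModelSpec(seed=0),
                            n_dev=10, events_dev=5, varcov=np.array([[1.0]]))
        d = parametric_sample(m, np.zeros(0), S=100000, seed=4)
        assert np.mean(logit(d.samples)) == pytest.approx(0.0, abs=0.01)

    def test_requires_varcov(self):
        m = make_model()
        with pytest.raises(InputError, match="no covariance"):
            parametric_sample(m, np.zeros(1), S=10, seed=0)


class TestWald:
    def test_closed_form_intercept_only(self):
        m = FittedRiskModel(intercept=0.0, coefficients=np.zeros(0),
                            predictor_names=[], spec=ModelSpec(seed=0),
                            n_dev=10, events_dev=5, varcov=np.array([[1.0]]))
        iv = wald_interval(m, np.zeros(0), 0.95)
        assert iv.lower == pytest.approx(expit(-1.959964), abs=1e-6)
        assert iv.upper == pytest.approx(expit(1.959964), abs=1e-6)
        # to the printed precision: expit(-1.959964) = 0.12347...
        assert iv.lower == pytest.approx(0.1234, abs=1e-4)
        assert iv.upper == pytest.approx(0.8766, abs=1e-4)

    def test_zero_se_degenerates_to_plug_in(self):
        m = make_model(intercept=logit(0.4), varcov=np.zeros((2, 2)))
        iv = wald_interval(m, np.zeros(1), 0.95)
        assert iv.lower == iv.upper == pytest.approx(0.4, abs=1e-12)

    def test_width_monotone_in_level(self, small_model):
        x = np.array([0.3, -0.2])
        w50 = wald_interval(small_model, x, 0.50).width
        w95 = wald_interval(small_model, x, 0.95).width
        assert w95 >= w50

    def test_level_validation(self, small_model):
        with pytest.raises(InputError, match="level"):
            wald_interval(small_model, np.zeros(2), 1.5)


class TestSummarize:
    def test_small_sample_examples(self):
        d = RiskDistribution(samples=[0.2, 0.4, 0.6], source="bootstrap")
        s = summarize(d)
        assert s.mean == pytest.approx(0.4)
        assert s.median == pytest.approx(0.4)
        d2 = RiskDistribution(samples=[0.3] * 7, source="bootstrap")
        s2 = summarize(d2)
        assert s2.mean == s2.median == pytest.approx(0.3)
        assert s2.mode == pytest.approx(0.305)  # midpoint of bin [0.30, 0.31)
        assert s2.intervals[0.95].lower == s2.intervals[0.95].upper == 0.3

    def test_uniform_quantiles(self):
        rng = np.random.default_rng(8)
        d = RiskDistribution(samples=rng.uniform(size=100000),
                             source="parametric")
        iv = summarize(d).intervals[0.95]
        assert iv.lower == pytest.approx(0.025, abs=0.005)
        assert iv.upper == pytest.approx(0.975, abs=0.005)

    def test_samples_must_be_risks(self):
        with pytest.raises(InputError):
            RiskDistribution(samples=[0.5, 1.2], source="bootstrap")
        with pytest.raises(InputError):
            RiskDistribution(samples=[], source="bootstrap")


class TestInstabilityDiagnostics:
    def test_identical_members_give_zero_mad(self, small_cohort, small_model):
        ens = BootstrapEnsemble(original=small_model, members=[small_model] * 4,
                                seed=0)
        out = instability_diagnostics(ens, small_cohort, threshold=0.5)
        # to within BLAS summation-order noise
        np.testing.assert_allclose(out["table"]["mad"], 0.0, atol=1e-12)
        assert np.all(out["table"]["instability_index"] == 0.0)

    def test_mad_nonnegative_and_payloads_present(self, small_cohort):
        ens = bootstrap_ensemble(small_cohort, ModelSpec(penalty="none", seed=0),
                                 B=20, seed=2)
        out = instability_diagnostics(ens, small_cohort, threshold=0.3)
        assert np.all(out["table"]["mad"] >= 0.0)
        assert out["scatter"]["bootstrap"].shape == (small_cohort.n, 20)
        # index is the mass opposite the *plug-in* decision, so it can exceed
        # 0.5 when the bootstrap majority disagrees with the plug-in model
        ci = out["classification_instability"]
        assert np.all((ci["instability_index"] >= 0)
                      & (ci["instability_index"] <= 1.0))


class TestEnsembleIO:
    def test_roundtrip_bit_exact_and_same_samples(self, small_cohort, tmp_path):
        ens = bootstrap_ensemble(small_cohort, ModelSpec(penalty="none", seed=0),
                                 B=5, seed=3)
        path = tmp_path / "ens.json"
        export_ensemble(ens, path)
        back = import_ensemble(path)
        assert back.B == ens.B
        assert back.redraw_count == ens.redraw_count
        for m1, m2 in zip(ens.members, back.members):
            assert m1.intercept == m2.intercept
            np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
        x = np.array([0.5, -0.5])
        np.testing.assert_array_equal(
            sample_bootstrap_distribution(ens, x).samples,
            sample_bootstrap_distribution(back, x).samples)

    def test_unknown_version_and_truncation_rejected(self, small_cohort,
                                                     tmp_path):
        ens = bootstrap_ensemble(small_cohort, ModelSpec(penalty="none", seed=0),
                                 B=3, seed=3)
        path = tmp_path / "ens.json"
        export_ensemble(ens, path)
        obj = json.loads(path.read_text())
        obj["format_version"] = 99
        path.write_text(json.dumps(obj))
        with pytest.raises(SerializationError, match="format_version"):
            import_ensemble(path)
        obj["format_version"] = 1
        obj["members"] = obj["members"][:2]  # truncated
        path.write_text(json.dumps(obj))
        with pytest.raises(SerializationError, match="truncated"):
            import_ensemble(path)
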