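import numpy as np
import pytest

from riskuq import CohortData, ModelSpec, fit_model


@pytest.fixture
def two_by_two():
    """Binary predictor: events 30/100 when x=1, 10/100 when x=0.
    Logistic MLE has closed form: slope log[(30/70)/(10/90)],
    intercept log(10/90)."""
    X = np.array([[1.0]] * 100 + [[0.0]] * 100)
    y = np.array([1] * 30 + [0] * 70 + [1] * 10 + [0] * 90)
    return CohortData(X=X, y=y, predictor_names=["x"])


@pytest.fixture
def small_cohort():
    """n=400 two-predictor cohort from a known logistic truth."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(400, 2))
    p = 1 / (1 + np.exp(-(-0.5 + X @ np.array([1.0, -0.7]))))
    y = rng.binomial(1, p)
    return CohortData(X=X, y=y, predictor_names=["a", "b"])


@pytest.fixture
def small_model(small_cohort):
    return fit_model(small_cohort, ModelSpec(penalty="none", seed=0))
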