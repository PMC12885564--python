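import pytest

import wisfc as w


@pytest.fixture(scope="session")
def worked_example():
    """Two-feature, five-model rank matrix (blood pressure vs cholesterol)."""
    return w.load_worked_example()


@pytest.fixture(scope="session")
def churn_outputs():
    """Three-model churn importance fixture over six features."""
    return w.load_churn_example()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (300 rows, 20 features, 5 informative)."""
    return w.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def harness_result(cohort):
    """One harness run on the default cohort, shared across tests."""
    return w.run_harness(cohort.X, cohort.y, cv=w.CVConfig(folds=3, seed=11))
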