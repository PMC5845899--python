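import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def exp2_cohort():
    """19 simulated subjects on the LAB design at default truth."""
    from polystream import TruthParams, simulate_cohort

    truth = TruthParams(n_subjects=19, seed=11)
    trials, subjects = simulate_cohort(truth, group="LAB")
    return truth, trials, subjects


@pytest.fixture(scope="session")
def exp1_cohort():
    """29 simulated subjects on the full experiment-1 design."""
    from polystream import exp1_default_truth, simulate_cohort

    truth = exp1_default_truth(n_subjects=29, seed=12)
    trials, subjects = simulate_cohort(truth)
    return truth, trials, subjects


@pytest.fixture(scope="session")
def exp2_cells(exp2_cohort):
    from polystream import aggregate_counts

    _, trials, _ = exp2_cohort
    return aggregate_counts(trials)
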