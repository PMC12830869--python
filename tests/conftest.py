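import numpy as np
import pytest

from oxcircuit import (
    TwoStateSummary,
    invert_summary,
    reference_cohort_spec,
    reference_summary,
    rest_work_recovery,
)


@pytest.fixture(scope="session")
def young_summary() -> TwoStateSummary:
    return reference_summary("young")


@pytest.fixture(scope="session")
def old_summary() -> TwoStateSummary:
    return reference_summary("old")


@pytest.fixture(scope="session")
def young_cohort_spec():
    return reference_cohort_spec("young")


@pytest.fixture(scope="session")
def protocol():
    return rest_work_recovery()


@pytest.fixture(scope="session")
def young_params(young_summary):
    """Young-cohort circuit parameters, per-state effective capacitance."""
    return invert_summary(young_summary)


def random_parameter_sets(n: int, seed: int):
    """Physiological-range random (Pa, Rd, Rm, C) arrays for identity checks."""
    rng = np.random.default_rng(seed)
    return {
        "Pa": rng.uniform(20.0, 150.0, n),
        "Rd": np.exp(rng.uniform(np.log(0.05), np.log(20.0), n)),
        "Rm": np.exp(rng.uniform(np.log(0.05), np.log(20.0), n)),
        "C": rng.uniform(1.0, 100.0, n),
    }
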