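import numpy as np
import pytest

from epinhs.cohort_model import OVERALL, Cohort, Patient, SeizureHistory
from epinhs.synthetic_cohort import GeneratorConfig, generate_cohort


def make_history(pid: str, sf: list[int], start: int = 1) -> SeizureHistory:
    return SeizureHistory(pid, {OVERALL: {start + i: v for i, v in enumerate(sf)}})


def make_cohort(sf_by_pid: dict[str, list[int]], start: int = 1) -> Cohort:
    cohort = Cohort()
    for pid, sf in sf_by_pid.items():
        cohort.patients[pid] = Patient(
            patient_id=pid, observation_start_month=start,
            observation_end_month=start + len(sf) - 1,
            has_epilepsy=any(v > 0 for v in sf))
        cohort.histories[pid] = make_history(pid, sf, start)
    return cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort (101 patients)."""
    cohort, truth = generate_cohort(GeneratorConfig(n_patients=101, seed=5))
    return cohort, truth


@pytest.fixture(scope="session")
def large_cohort():
    """Larger cohort used for parameter-recovery checks."""
    cohort, truth = generate_cohort(GeneratorConfig(n_patients=300, seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
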