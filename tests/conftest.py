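import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mmgstrat.cohort import Cohort, NerveMeasurement, PatientRecord
from mmgstrat.simulate import SyntheticConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_patient(pid="P1", nerve_pairs=((9.0, 3.0),), region="lumbar",
                 nps_pre=6, nps_6wk=2):
    nerves = tuple(
        NerveMeasurement(pid, f"L{i + 3}", pre, post)
        for i, (pre, post) in enumerate(nerve_pairs)
    )
    return PatientRecord(pid, region, nps_pre, nps_6wk, nerves)


@pytest.fixture
def single_patient_cohort():
    return Cohort(patients=(make_patient(),))


@pytest.fixture(scope="session")
def demo_cohort():
    """Study-scale synthetic cohort, fixed seed, shared across tests."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def demo_metrics(demo_cohort):
    from mmgstrat.metrics import compute_metrics

    return compute_metrics(demo_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
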