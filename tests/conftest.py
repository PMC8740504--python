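import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from refsurv import RateTable, Subject

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_subjects(times, events, age=60.0, date=2009.5, stratum=None, rate_keys=None):
    """Small-cohort helper with shared demographics."""
    return [
        Subject(
            id=i, time=float(t), event=int(e),
            age_at_diagnosis=age, diagnosis_date=date,
            rate_keys=dict(rate_keys or {}), standard_stratum=stratum,
        )
        for i, (t, e) in enumerate(zip(times, events))
    ]


@pytest.fixture
def const_table():
    return RateTable.constant(0.02)


@pytest.fixture
def zero_table():
    return RateTable.zero()


@pytest.fixture
def tiny_cohort():
    # deaths at 1 and 2, censored at 3
    return make_subjects([1.0, 2.0, 3.0], [1, 1, 0])
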