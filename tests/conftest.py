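from datetime import datetime

import numpy as np
import pytest
from hypothesis import settings

import ccmpipe as cp

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

T0 = datetime(2024, 1, 1, 9, 0)  # lights-on at experiment start


def make_series(counts, fly_id="fly", origin=T0):
    return cp.BeamBreakSeries(fly_id=fly_id, origin=origin, counts=np.asarray(counts))


@pytest.fixture(scope="session")
def sched_control():
    return cp.LightSchedule.ld(T0, period_hours=24.0, photoperiod_hours=12.0)


@pytest.fixture(scope="session")
def sched_ccm():
    return cp.LightSchedule.ld(T0, period_hours=28.0, photoperiod_hours=14.0)


@pytest.fixture(scope="session")
def small_cohort(sched_control, sched_ccm):
    """12 flies/arm under default generative parameters, fixed seed."""
    cohort, truths = cp.simulate_cohort(
        12, cp.SimParams(), sched_control, sched_ccm, seed=11
    )
    return cohort, truths
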