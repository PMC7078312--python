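import numpy as np
import pytest

from selfworth import (
    ChoiceParams,
    SelfWorthParams,
    TaskDesign,
    make_schedule,
)
from selfworth.cohort import simulate_subject


@pytest.fixture(scope="session")
def default_design() -> TaskDesign:
    return TaskDesign()


@pytest.fixture(scope="session")
def default_schedule(default_design):
    return make_schedule(default_design, seed=11)


@pytest.fixture(scope="session")
def subject_factory(default_design):
    """Simulate a subject on a fresh seeded schedule; returns the trial log."""

    def make(
        eta=0.05, beta=8.0, v0_hi=0.8, v0_lo=0.2,
        w0=0.7, w1=0.05, gamma=0.5, sigma=0.05,
        schedule_seed=0, agent_seed=0, design=None,
    ):
        cp = ChoiceParams(eta=eta, beta=beta, v0_hi=v0_hi, v0_lo=v0_lo)
        sp = SelfWorthParams(w0=w0, w1=w1, gamma=gamma, sigma=sigma)
        sched = make_schedule(design or default_design, schedule_seed)
        return simulate_subject(cp, sp, sched, agent_seed)

    return make
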