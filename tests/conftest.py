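import numpy as np
import pytest

from abastream.model_core import StimulusDescriptor, get_preset
from abastream.simulate import run_trial
from abastream.synth_behavior import generate_cohort


@pytest.fixture(scope="session")
def efix():
    return get_preset("efix_ilcl")


@pytest.fixture(scope="session")
def edyn():
    return get_preset("edyn_igbl")


@pytest.fixture(scope="session")
def stim_ambiguous():
    """The bistable reference stimulus: Δf = 5 st at PR = 8 Hz."""
    return StimulusDescriptor(delta_f=5.0, pr=8.0, duration=60.0)


@pytest.fixture(scope="session")
def short_trace(efix, stim_ambiguous):
    """One fully recorded 60 s trial at the reference stimulus."""
    return run_trial(stim_ambiguous, efix, seed=1234, record="full")


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic behavioral cohort (15 subjects x 3 reps x 8 Δf)."""
    return generate_cohort(seed=20240917)
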