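import numpy as np
import pytest

import reachadapt as ra
from reachadapt.models import ModelSpec


@pytest.fixture(scope="session")
def exp1_schedule():
    return ra.build_schedule(1, seed=11)


@pytest.fixture(scope="session")
def state_aim_spec():
    return ModelSpec("state_aim_scaling", n_states=2)


@pytest.fixture(scope="session")
def state_aim_params():
    return ra.synth.default_generator_params("state_aim_scaling")


@pytest.fixture(scope="session")
def noiseless_dataset(exp1_schedule, state_aim_spec, state_aim_params):
    return ra.generate_participant(state_aim_spec, state_aim_params,
                                   exp1_schedule, ra.NoiseModel(0.0, 0.0),
                                   seed=1)
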