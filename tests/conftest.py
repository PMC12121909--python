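import dataclasses

import numpy as np
import pytest

from ecomotor.body import BodyParams, default_body
from ecomotor.control import execute_trial
from ecomotor.feedback import FeedbackGains
from ecomotor.internal_model import InternalDynamicsModel
from ecomotor.plan import plan_from_offsets


@pytest.fixture(scope="session")
def body() -> BodyParams:
    return default_body()


@pytest.fixture(scope="session")
def unperturbed(body) -> BodyParams:
    return dataclasses.replace(body, perturbation_gain_K=0.0)


def make_plan(body, offsets=(0.0, 0.0, 0.0), **kwargs):
    start = (body.stance_x, body.leg_length_squat)
    end = (body.stance_x, body.leg_length_stand)
    return plan_from_offsets(offsets, start=start, end=end, **kwargs)


@pytest.fixture(scope="session")
def adapted_model(body, unperturbed):
    """Internal model trained to convergence on the pulled environment."""
    model = InternalDynamicsModel(params=unperturbed, learning_rate_eta=0.2)
    plan = make_plan(body, (0.05, 0.09, 0.10))
    gains = FeedbackGains()
    for _ in range(15):
        execute_trial(plan, body, model, gains, learn=True)
    return model
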