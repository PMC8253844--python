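import numpy as np
import pytest

from wormmotor.connectome import NeuronIndexMap, synthesize_connectome
from wormmotor.dynamics import CommandSchedule
from wormmotor.training import TrainingConfig, initialize


@pytest.fixture(scope="session")
def standard_map():
    return NeuronIndexMap.standard()


@pytest.fixture(scope="session")
def tiny_map():
    """A 3-segment circuit: 7 neurons (one per class), ~11 muscles."""
    return NeuronIndexMap.scaled(3)


@pytest.fixture(scope="session")
def tiny_mask(tiny_map):
    return synthesize_connectome(tiny_map, density=0.7, locality_span=2,
                                 seed=7, proprio_span=2)


@pytest.fixture(scope="session")
def tiny_schedule():
    return CommandSchedule((0.0, 1.0), 2.0)   # 40 steps at 0.05 s


@pytest.fixture
def tiny_params(tiny_mask):
    # larger lag constants than the training draw, so the dynamics move
    cfg = TrainingConfig(init_tau=(0.5, 5.0))
    return initialize(tiny_mask, cfg, seed=3)


def make_instance(seed, n_segments=3, tau_range=(0.5, 5.0)):
    """Random small problem instance: mask, params, schedule, teacher."""
    rng = np.random.default_rng(seed)
    imap = NeuronIndexMap.scaled(n_segments)
    mask = synthesize_connectome(imap, density=0.7,
                                 locality_span=max(2, n_segments // 2),
                                 seed=seed, proprio_span=2)
    cfg = TrainingConfig(init_tau=tau_range)
    params = initialize(mask, cfg, seed=seed)
    schedule = CommandSchedule((0.0, 1.0), 2.0)
    n_steps = round(schedule.total_time / params.fs)
    teacher_d = rng.uniform(0.25, 0.75, (n_steps, imap.n_muscles))
    return mask, params, schedule, teacher_d
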