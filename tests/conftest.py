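import numpy as np
import pytest

from hingecal.kinematics import SampleBatch
from hingecal.simulate import (SimConfig, generate_trajectory, motion_spec,
                               synthesize_measurements)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def noisefree_cfg():
    return SimConfig(seed=7).noiseless()


def make_motion_batch(index, duration, cfg):
    truth = generate_trajectory(motion_spec(index, duration), cfg)
    return truth, synthesize_measurements(truth, cfg)


@pytest.fixture(scope="session")
def planar_batch(sim_cfg):
    """Noisy slow simultaneous-planar motion (informative)."""
    return make_motion_batch(5, 10.0, sim_cfg)


@pytest.fixture(scope="session")
def sequential_batch(sim_cfg):
    """Noisy slow sequential rotation (informative)."""
    return make_motion_batch(3, 10.0, sim_cfg)


@pytest.fixture(scope="session")
def stiff_batch(sim_cfg):
    """Noisy stiff-joint rotation (non-informative)."""
    return make_motion_batch(2, 10.0, sim_cfg)


@pytest.fixture
def random_batch(rng):
    """Small batch of unstructured random measurements (no joint model)."""
    n = 40
    return SampleBatch(np.arange(n) / 50.0,
                       rng.standard_normal((n, 3)),
                       rng.standard_normal((n, 3)),
                       5.0 * rng.standard_normal((n, 3)),
                       5.0 * rng.standard_normal((n, 3)))
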