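import numpy as np
import pytest

from motionsentry import (
    SyntheticSpec,
    make_corpus,
    make_skeleton,
)
from motionsentry.motion import MotionSequence


@pytest.fixture(scope="session")
def skeleton():
    return make_skeleton(15)


@pytest.fixture(scope="session")
def small_corpus():
    """24 labeled sequences at the default study conditions (seeded)."""
    return make_corpus(SyntheticSpec(n_sequences=24, seed=11))


@pytest.fixture(scope="session")
def noiseless_corpus():
    return make_corpus(SyntheticSpec(n_sequences=16, noise_sd=0.0, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_sequence(positions, dt=1.0, vertical_axis=-1):
    """Helper: wrap a (T, J, D) array into a MotionSequence."""
    positions = np.asarray(positions, dtype=float)
    T, J, _ = positions.shape
    return MotionSequence(
        times=np.arange(T) * dt,
        positions=positions,
        joint_names=[f"j{i}" for i in range(J)],
        vertical_axis=vertical_axis,
    )


@pytest.fixture()
def line_sequence():
    """x_t = (t, 0, 0) at dt = 1."""
    pos = np.zeros((5, 1, 3))
    pos[:, 0, 0] = np.arange(5)
    return make_sequence(pos)
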