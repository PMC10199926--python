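import numpy as np
import pytest

from runtumble import (
    PAPER_JUMP_LAW,
    PAPER_POSITION_LAW,
    PAPER_PROFILE,
    DomainConfig,
    TrajectoryGenConfig,
    gen_trajectory,
)


@pytest.fixture(scope="session")
def paper_law():
    return PAPER_JUMP_LAW


@pytest.fixture(scope="session")
def paper_profile():
    return PAPER_PROFILE


@pytest.fixture(scope="session")
def paper_poslaw():
    return PAPER_POSITION_LAW


@pytest.fixture(scope="session")
def gradient_gen_config():
    """Generator settings emulating the gradient-chamber experiment with the
    published parameters (a, l0, b) = (0.063, 12.9, 0.295) and mild tracking
    noise on jump lengths."""
    return TrajectoryGenConfig(
        poslaw=PAPER_POSITION_LAW,
        b=0.295,
        n_cycles=2500,
        domain=DomainConfig(100.0),
        tumble_duration=1.0,
        length_noise_sd=2.0,
        seed=2024,
    )


@pytest.fixture(scope="session")
def gradient_trajectory(gradient_gen_config):
    """A long synthetic gradient-chamber recording plus its ground truth."""
    return gen_trajectory(gradient_gen_config)
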