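import numpy as np
import pytest

from drowsekit.synthetic import SimConfig, simulate_session


@pytest.fixture(scope="session")
def short_strong_session():
    """A small strong-effect session: wake 60 / drowsy 30 / wake 60 /
    drowsy 25 / wake 60 seconds, pronounced EEG state contrast."""
    config = SimConfig.strong_effect(
        seed=3,
        duration=400.0,
        episode_schedule=[
            ("wake", 60.0),
            ("drowsy", 30.0),
            ("wake", 60.0),
            ("drowsy", 25.0),
            ("wake", 60.0),
        ],
    )
    return simulate_session(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
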