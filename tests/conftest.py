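import numpy as np
import pytest

from seadbs.config import EnvConfig, TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def surrogate_cfg():
    return EnvConfig(backend="surrogate", condition="parkinsonian", seed=0)


@pytest.fixture
def short_train_cfg():
    return TrainConfig(
        n_episodes=2,
        env=EnvConfig(backend="surrogate", condition="parkinsonian", seed=0),
        seed=0,
    )


@pytest.fixture(scope="session")
def network_state():
    """One settled parkinsonian network shared by structural tests."""
    from seadbs.env.network import build_network, integrate

    cfg = EnvConfig(condition="parkinsonian", seed=0)
    state = build_network(cfg)
    integrate(state, 100.0)
    return state
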