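import numpy as np
import pytest

import iwavesim as iw
from iwavesim.config import ModelConfig
from iwavesim.network import Connectome

TINY_SCALE = 0.05
TINY_SEED = 1234


def make_toy_connectome(n, pre=(), post=(), weight=(), delay=(), dt=0.1,
                        positions=None, group_name="2/3E"):
    """Hand-built single-group connectome for engine-level tests."""
    if positions is None:
        positions = np.zeros((n, 3))
    return Connectome(
        pre=np.asarray(pre, np.int32), post=np.asarray(post, np.int32),
        weight=np.asarray(weight, np.float32),
        delay_ms=np.asarray(delay, np.float32),
        group_names=[group_name], group_counts=np.array([n], np.int64),
        group_of=np.zeros(n, np.int16), positions=np.asarray(positions, float),
        dt=dt)


def quiet_config(**sim_overrides) -> ModelConfig:
    """Config with no background drive and deterministic initial conditions."""
    cfg = ModelConfig()
    cfg.external.rate_hz = 0.0
    cfg.sim.init_voltage = "reset"
    cfg.sim.analysis_start = 0.0
    for key, value in sim_overrides.items():
        setattr(cfg.sim, key, value)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    return iw.make_fixture_config(TINY_SCALE, seed=TINY_SEED)


@pytest.fixture(scope="session")
def tiny_net(tiny_cfg):
    return iw.build_network(tiny_cfg)
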