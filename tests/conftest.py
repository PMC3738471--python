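import numpy as np
import pytest

from betacol import SimConfig, build_two_column_network, integrate, load_model
from betacol.network import single_cell_network


@pytest.fixture(scope="session")
def model():
    return load_model()


@pytest.fixture(scope="session")
def net(model):
    """One realized two-column network (seed 0)."""
    return build_two_column_network(model, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def quiet_cell(config, pop, drive=0.0, **comp_overrides):
    """Single cell of one class with zero tonic noise and a fixed drive."""
    comps = config.raw["populations"][pop]["compartments"]
    ov = {
        "populations": {
            pop: {
                "compartments": {
                    k: dict(comp_overrides, tonic_mean=drive, tonic_std=0.0) for k in comps
                }
            }
        }
    }
    return single_cell_network(config.with_overrides(ov), pop)


def run_single(network, duration=200.0, seed=0, stimuli=(), record_v=True, v_dt=0.1):
    return integrate(
        network,
        list(stimuli),
        SimConfig(duration=duration, seed=seed, record_v=record_v, v_dt=v_dt, record_lfp=False),
    )
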