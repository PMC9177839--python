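import numpy as np
import pytest

from trackiba.simulate import (Colony, ErrorParams, GroupSpec, MovementParams,
                               SamplingParams, SimulationConfig,
                               simulate_dataset)

# ~300 km at latitude -33.3: 1 deg lon ~ 92.9 km
LON_300KM = 3.23


@pytest.fixture(scope="session")
def small_cfg():
    """One colony, six birds, ~18-day trips: cheap enough for most tests."""
    return SimulationConfig(
        colonies=(Colony("Isle A", 18.0, -33.3),),
        groups=(GroupSpec("Isle A", "pre_moult", 2018, 6),),
        movement=MovementParams(trip_duration_mean_days=18.0,
                                trip_duration_sd_days=2.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def two_colony_cfg():
    """Two colonies ~300 km apart, five birds each."""
    return SimulationConfig(
        colonies=(Colony("Isle A", 18.0, -33.3),
                  Colony("Isle B", 18.0 + LON_300KM, -33.3)),
        groups=(GroupSpec("Isle A", "pre_moult", 2018, 5),
                GroupSpec("Isle B", "pre_moult", 2018, 5)),
        movement=MovementParams(trip_duration_mean_days=15.0,
                                trip_duration_sd_days=1.0),
        seed=21,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
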