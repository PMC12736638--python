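import numpy as np
import pytest
from hypothesis import settings

import dmwi
from dmwi.reconstruction import water_permittivity_fn

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def water():
    return dmwi.WATER_DEBYE["stogryn1971"]


@pytest.fixture(scope="session")
def array():
    return dmwi.build_array()


@pytest.fixture(scope="session")
def coarse_grid():
    """2-mm ROI grid: fast but fine enough to localize an 8-mm inclusion."""
    return dmwi.build_grid(100.0, 2.0)


@pytest.fixture(scope="session")
def full_grid():
    """The production 1-mm ROI grid (~31 000 focal points)."""
    return dmwi.build_grid(100.0, 1.0)


@pytest.fixture(scope="session")
def medium(water):
    return water_permittivity_fn(water, 25.0)


@pytest.fixture(scope="session")
def quiet_acq():
    return dmwi.AcquisitionSpec(noise_floor_db=None, seed=11)


@pytest.fixture(scope="session")
def scene_template():
    return dmwi.PhantomScene(inclusion_temperature_c=40.5)


@pytest.fixture(scope="session")
def noise_free_series(scene_template, array, quiet_acq):
    """Noise-free cooling series down to dT = 0.9 C (10 acquisitions)."""
    return dmwi.cooling_series(
        scene_template, array, quiet_acq, t_stop_c=39.6, timing_noise=False
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
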