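import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nichemetry as nm
from nichemetry.phantom import ImagingConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_model() -> nm.ScaffoldModel:
    return nm.build_scaffold()


@pytest.fixture(scope="session")
def mini_model() -> nm.ScaffoldModel:
    """Single set, two walls, one unit: the smallest meaningful scaffold."""
    params = nm.ScaffoldParams(
        walls_per_set=2, n_sets=1, units_per_wall=1, total_depth=None
    )
    return nm.build_scaffold(params)


@pytest.fixture(scope="session")
def unit1_imaging() -> ImagingConfig:
    """Field of view cropped to the canonical unit (x in [0, 210] µm)."""
    return ImagingConfig(fov=(210.0, 520.0))


@pytest.fixture(scope="session")
def endmembers_405():
    return nm.default_endmembers(nm.LAMBDA_405)


@pytest.fixture(scope="session")
def unit1_mask(default_model, unit1_imaging):
    return nm.rasterize(default_model, unit1_imaging.pixel_size, fov=unit1_imaging.fov)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
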