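import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ivivckit.dissolution import DissolutionModel

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

#: the standard dissolution sampling grid, minutes
DISS_GRID_MIN = np.array([15, 30, 45, 60, 90, 120, 180, 240, 360], float)

#: the standard PK sampling grid, minutes
PK_GRID_MIN = np.array(
    [15, 30, 45, 60, 90, 120, 150, 180, 240, 360, 480, 720, 1440], float)


def make_dissolution(model: str, **params) -> DissolutionModel:
    """A ready-to-evaluate dissolution model with known parameters."""
    fit = DissolutionModel(model=model)
    fit.params_ = dict(params)
    return fit


@pytest.fixture
def diss_grid_min():
    return DISS_GRID_MIN.copy()


@pytest.fixture
def pk_grid_min():
    return PK_GRID_MIN.copy()
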