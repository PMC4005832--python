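import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ldmkit import calibrate_from_extents, synthesize_ldm

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: The three-spot worked-example configuration: 5x5 templates on a 13x12
#: grid, centroids (7,5), (5,8), (9,7) in the original 1-based grid,
#: converted here to 0-based (row, col).
EXAMPLE_SPOTS = [(6.0, 4.0), (4.0, 7.0), (8.0, 6.0)]
EXAMPLE_DIMS = (13, 12)
EXAMPLE_TEMPLATE = 5


@pytest.fixture
def worked_spots():
    return list(EXAMPLE_SPOTS)


@pytest.fixture
def worked_ldm():
    return synthesize_ldm(EXAMPLE_SPOTS, EXAMPLE_DIMS, EXAMPLE_TEMPLATE)


@pytest.fixture
def bed_calibration():
    """Reference-bed calibration: 140 mm == 397 px, 12 mm laser window."""
    return calibrate_from_extents(140.0, 397.0, 12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
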