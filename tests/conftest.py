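import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stemkin as sk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Reference-cohort mean-scale parameters: velocity 0.368 mm/s, trapping
# 0.00084 1/mm, 4-minute administration, six ROIs 5 mm apart up the stem.
MEAN_VELOCITY_MM_S = 0.368
MEAN_TRAPPING_PER_MM = 0.00084
MEAN_ADMIN_DURATION_S = 240.0
ROI_POSITIONS_MM = tuple(5.0 + 5.0 * np.arange(6))


@pytest.fixture(scope="session")
def mean_truth() -> sk.SimTruth:
    return sk.SimTruth(
        velocity_mm_s=MEAN_VELOCITY_MM_S,
        s_per_mm=MEAN_TRAPPING_PER_MM,
        admin_duration_s=MEAN_ADMIN_DURATION_S,
        roi_positions_mm=ROI_POSITIONS_MM,
        noise_cv=0.0,
        rng_seed=1,
    )


@pytest.fixture(scope="session")
def clean_plant(mean_truth) -> sk.SimPlant:
    """A noise-free plant observed through the standard frame schedule."""
    return sk.observe_plant(mean_truth)


@pytest.fixture(scope="session")
def clean_result(clean_plant) -> sk.PlantResult:
    return sk.analyze_plant(clean_plant.curves, clean_plant.manifest)
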