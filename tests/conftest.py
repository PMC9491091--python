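import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neuropet import make_toy_atlas, acquisition_schedule, reference_curve_fine, reference_tac

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    return acquisition_schedule()


@pytest.fixture(scope="session")
def atlas32():
    return make_toy_atlas((32, 32, 32))


@pytest.fixture(scope="session")
def atlas16():
    return make_toy_atlas((16, 16, 16))


@pytest.fixture(scope="session")
def ref_tac(schedule):
    return reference_tac(schedule)


@pytest.fixture(scope="session")
def fine_ref(schedule):
    return reference_curve_fine(schedule)


@pytest.fixture(scope="session")
def label_dvr_unit():
    """All regions at DVR 1 except choroid plexus at the healthy-group level."""
    return {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0, 5: 0.856}


def make_noise_maps(mask, n_subjects, seed, sd=0.03, mean=1.0):
    """Independent Gaussian DVR-like maps, NaN outside the mask."""
    rng = np.random.default_rng(seed)
    return [
        np.where(mask, mean + sd * rng.standard_normal(mask.shape), np.nan)
        for _ in range(n_subjects)
    ]
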