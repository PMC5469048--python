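import numpy as np
import pytest

from visuomotor import ExperimentDesign, make_cohort
from visuomotor.model import Doppelganger


@pytest.fixture(scope="session")
def design():
    """One fixed 24-test-block design shared by read-only tests."""
    return ExperimentDesign.sample(np.random.default_rng(42))


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(3, rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def light_fits(small_cohort):
    """Quickly fitted doppelgangers of all three orders for the small cohort."""
    fits = {}
    for sd in small_cohort:
        for order in ("zeroth", "first", "second"):
            rng = np.random.default_rng(1000 + sd.profile.subject_id)
            fits[(sd.profile.subject_id, order)] = Doppelganger.from_subject(sd, order).fit(
                rng, mc_blocks=500, n_starts=2, rounds=1, sigma_fit_reps=100,
                calibration_reps=500,
            )
    return fits
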