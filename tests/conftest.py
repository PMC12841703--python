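import numpy as np
import pytest

from preecv import PredictorProfile, Parity, Presentation, published_cohort_fixture


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 100-patient published-margins cohort."""
    return published_cohort_fixture()


@pytest.fixture
def max_profile():
    return PredictorProfile(
        parity=Parity.MULTIPAROUS,
        presentation=Presentation.TRANSVERSE,
        engaged=False,
        palpable_head=True,
        efw_ge_10th_percentile=True,
        mvp_ge_4cm=True,
        placenta_posterior=True,
        tocolysis=True,
    )


@pytest.fixture
def min_profile():
    return PredictorProfile(
        parity=Parity.NULLIPAROUS,
        presentation=Presentation.FRANK_BREECH,
        engaged=True,
        palpable_head=False,
        efw_ge_10th_percentile=False,
        mvp_ge_4cm=False,
        placenta_posterior=False,
        tocolysis=False,
    )


def random_binary_dataset(rng: np.random.Generator, n: int):
    """Random predictions/outcomes with both classes guaranteed present."""
    preds = rng.random(n)
    y = rng.integers(0, 2, n)
    y[0], y[1] = 0, 1
    return preds, y
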