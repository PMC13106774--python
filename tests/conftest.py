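import warnings

import numpy as np
import pytest

from cvdcea.cohort import generate_cohort
from cvdcea.params import PlaceholderWarning, bundled_config_path, load_parameters


@pytest.fixture(scope="session")
def scotland():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PlaceholderWarning)
        return load_parameters(bundled_config_path("scotland"))


@pytest.fixture(scope="session")
def china():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PlaceholderWarning)
        return load_parameters(bundled_config_path("china"))


@pytest.fixture(scope="session")
def cohort500(scotland):
    return generate_cohort(500, scotland.generator, seed=11)


@pytest.fixture
def profile():
    from cvdcea.cohort import RiskProfile

    return RiskProfile(age=62.0, sex="male", sbp=148.0, tc=6.2, hdl=1.25,
                       cigs_per_day=10, diabetes=0, family_history_cvd=1, simd=35.0)


@pytest.fixture(autouse=True)
def _silence_placeholder_warning():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PlaceholderWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
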