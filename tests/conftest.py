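import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pqakin import reference

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def single_pk():
    return reference.SINGLE_DOSE_PK


@pytest.fixture
def multi_pk():
    return reference.MULTI_DOSE_PK


@pytest.fixture
def asn2():
    return reference.ASN_SITE_2


@pytest.fixture
def pyro():
    return reference.PYROGLUTAMATE


@pytest.fixture
def study_times():
    return np.asarray(reference.SINGLE_DOSE_SAMPLING_DAYS)
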