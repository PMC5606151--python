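import numpy as np
import pytest

from rpeakdet.synthetic import generate, preset


@pytest.fixture(scope="session")
def clean_fixture():
    return generate(preset("clean"), record_id="clean")


@pytest.fixture(scope="session")
def pvc_fixture():
    return generate(preset("pvc"), record_id="pvc")


@pytest.fixture(scope="session")
def mixed_fixture():
    return generate(preset("mixed_amplitude"), record_id="mixed")


@pytest.fixture(scope="session")
def drift_fixture():
    return generate(preset("drift"), record_id="drift")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
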