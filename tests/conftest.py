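import pytest

from kpdsim.calibration import phenotype_presets


@pytest.fixture(scope="session")
def presets():
    return phenotype_presets()


@pytest.fixture(scope="session")
def preset_A(presets):
    return presets["A"]


@pytest.fixture(scope="session")
def preset_B(presets):
    return presets["B"]


@pytest.fixture(scope="session")
def preset_C(presets):
    return presets["C"]


@pytest.fixture(scope="session")
def preset_D(presets):
    return presets["D"]
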