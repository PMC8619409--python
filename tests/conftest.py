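import pytest
from hypothesis import settings

from copycall import synthetic as syn

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_cfg() -> syn.SimulationConfig:
    return syn.SimulationConfig(seed=7, ct_noise_sd=0.0)


@pytest.fixture(scope="session")
def assay():
    return syn.default_assay()
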