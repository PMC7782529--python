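import pytest

from metallonet.synthetic_data import SynthesisConfig, gen_workspace


@pytest.fixture(scope="session")
def default_config() -> SynthesisConfig:
    return SynthesisConfig(seed=1)


@pytest.fixture(scope="session")
def workspace(default_config):
    """One shared synthetic study (seed 1) for the read-only tests."""
    return gen_workspace(default_config)
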