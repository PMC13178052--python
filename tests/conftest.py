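import pytest

from hfgap.records import load_codesets
from hfgap.synthetic import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def codesets():
    return load_codesets()


@pytest.fixture(scope="session")
def small_population():
    """A modest synthetic population shared by read-only tests."""
    config = GeneratorConfig(n_patients=2000, true_hf_prevalence=0.15,
                             coding_probability=0.7, seed=7)
    events, deaths, demographics, latent = generate_population(config)
    return config, events, deaths, demographics, latent
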