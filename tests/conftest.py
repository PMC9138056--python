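import pytest
from hypothesis import settings

from isoturn import paper_default_config, simulate_experiment

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_experiment():
    """Noise-free experiment at the study design: fits must recover truth exactly."""
    cfg = paper_default_config(seed=0, noise_sd=0.0, weight_cv=0.0)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noisy_experiment():
    """One experiment at the study's analytical noise level."""
    cfg = paper_default_config(seed=11)
    return simulate_experiment(cfg)
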