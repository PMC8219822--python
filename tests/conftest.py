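import pytest

from thermorep import GeneratorConfig, MCMCConfig, generate_study_dataset


@pytest.fixture(scope="session")
def default_corpus():
    """One default-configuration synthetic corpus (1,407 studies), fixed seed."""
    return generate_study_dataset(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced sampler schedule used throughout the tests."""
    return MCMCConfig(n_chains=4, n_draws=5_000, burn_in=1_000, thin=10, seed=7)


@pytest.fixture(scope="session")
def tiny_mcmc():
    """Very small schedule for smoke/degenerate-case tests."""
    return MCMCConfig(n_chains=2, n_draws=1_500, burn_in=500, thin=5, seed=11)
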