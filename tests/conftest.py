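import numpy as np
import pytest

from miaqsar import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset (fast to generate, low matrix rank)."""
    cfg = GeneratorConfig(
        n_compounds=12,
        glyph_alphabet_size=4,
        coverage_levels=4,
        noise_sd=0.0,
        seed=7,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the study's default generator settings."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
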