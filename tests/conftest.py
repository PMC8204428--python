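import numpy as np
import pytest

from rrbspower import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_synthetic():
    """The default-size synthetic cohort (50k sites x 125 samples), shared."""
    return generate(GeneratorConfig())


@pytest.fixture(scope="session")
def small_synthetic():
    """A small synthetic dataset for cheap structural tests."""
    return generate(GeneratorConfig(n_sites=2_000, n_samples=20, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
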