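import pytest

from agonet import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One fully simulated study shared (read-only) across test modules."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def chimera_rich_dataset():
    """A study with a high chimera rate for characterization statistics."""
    return generate_dataset(SimConfig(seed=2, chimera_rate=0.2))
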