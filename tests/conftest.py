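import pytest

from soilstoich.synthetic import SyntheticConfig, generate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One default-condition synthetic experiment (6 treatments × 5
    replicates × 2 phases), shared across read-only tests."""
    dataset, truth = generate_experiment(SyntheticConfig(seed=42))
    return dataset, truth


@pytest.fixture(scope="session")
def dataset(default_experiment):
    return default_experiment[0]
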