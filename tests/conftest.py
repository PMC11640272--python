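import pytest

from tcrscout.synthetic import build_worked_example, simulate_dataset


@pytest.fixture(scope="session")
def worked_example():
    """The deterministic worked-example dataset (built once per session)."""
    return build_worked_example()


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted simulated dataset for end-to-end tests."""
    return simulate_dataset(n_cells=300, n_clones=80, seed=12)
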