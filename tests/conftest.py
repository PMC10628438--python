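import numpy as np
import pytest

from scgrnet import synthetic


@pytest.fixture(scope="session")
def default_scenario():
    """The shared synthetic substrate: 600 cells, 1000 genes, 5 planted modules."""
    expr, truth = synthetic.simulate_counts(seed=1)
    return expr, truth


@pytest.fixture(scope="session")
def small_scenario():
    """A lighter scenario for stage-level tests."""
    expr, truth = synthetic.simulate_counts(
        n_genes=300, n_modules=3, module_size=40, cells_per_group=80, seed=7
    )
    return expr, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
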