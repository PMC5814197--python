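import numpy as np
import pytest

from stagetraj.design import default_design, make_design
from stagetraj.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def seven_stage_design():
    return default_design()


@pytest.fixture(scope="session")
def tiny_design():
    return make_design(["A", "B", "C"], [4, 4, 4])


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    return simulate_dataset(
        seed=7,
        expression_params=dict(n_genes=400, effect=1.5, sigma=0.5),
        interaction_params=dict(n_modules=2, module_size=6, intra_density=1.0,
                                background_density=0.01),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
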