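import numpy as np
import pytest

from comod import ExpressionMatrix, FixtureSpec, make_fixture


@pytest.fixture
def tiny_expr():
    """4 genes x 3 conditions with one missing cell."""
    values = np.array([
        [1.0, 2.0, 3.0],
        [1.1, 2.1, 2.9],
        [-1.0, 0.0, np.nan],
        [0.5, -0.5, 1.5],
    ])
    return ExpressionMatrix([f"g{i}" for i in range(4)],
                            [f"c{j}" for j in range(3)], values)


@pytest.fixture(scope="session")
def small_fixture():
    """Desk-scale fixture with 4 implanted modules, shared across tests."""
    spec = FixtureSpec(n_genes=80, n_conditions=30, n_modules=4,
                       genes_per_module=15, conditions_per_module=12,
                       rng_seed=7)
    return make_fixture(spec)
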