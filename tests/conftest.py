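import numpy as np
import pandas as pd
import pytest

from crosstalknet import (
    ExpressionMatrix,
    SimulationConfig,
    simulate_expression,
    simulate_genesets,
    simulate_network,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study: 400 genes, 150-node network, 20 exclusive focal genes."""
    return SimulationConfig(
        n_genes=400,
        network_size=150,
        n_exclusive_focal=20,
        n_degs_per_condition={
            "Doxo": 30, "E2": 25, "TNFa": 20,
            "Doxo+E2": 28, "Doxo+TNFa": 28, "Doxo+E2+TNFa": 45,
        },
        n_genesets=12,
        geneset_size_range=(8, 30),
        n_tissues=6,
        n_markers_per_tissue=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    expr, truth = simulate_expression(small_config)
    net = simulate_network(small_config, truth)
    collection = simulate_genesets(small_config, truth)
    return expr, truth, net, collection


def toy_expression() -> ExpressionMatrix:
    """4 genes x (2 conditions x 2 replicates), hand-set values."""
    values = pd.DataFrame(
        {
            "mock_r1": [3.0, 5.0, 1.0, 2.0],
            "mock_r2": [3.0, 5.0, 1.2, 2.0],
            "trt_r1": [5.0, 5.0, 1.1, 2.5],
            "trt_r2": [5.0, 5.0, 0.9, 2.4],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    design = pd.DataFrame(
        {
            "condition": ["mock", "mock", "trt", "trt"],
            "replicate": ["1", "2", "1", "2"],
        },
        index=pd.Index(values.columns, name="sample"),
    )
    return ExpressionMatrix(values=values, design=design)


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    return toy_expression()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
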