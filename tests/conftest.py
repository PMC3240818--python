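import numpy as np
import pandas as pd
import pytest

from remodelnet.synthetic import SimulationConfig, simulate_study


def small_config(**overrides) -> SimulationConfig:
    """A fast, fully-featured study configuration for unit tests."""
    base = dict(
        n_genes=800, n_high=16, n_low=16, n_de=40, n_annotated=120,
        n_overlap=16, overlap_direction=(11, 5), n_nodes=120,
        module_sizes=(10, 6), background_edge_prob=0.01, seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_study():
    return simulate_study(small_config(seed=11))


@pytest.fixture()
def toy_expr_samples():
    """4 genes x 6 samples with known class means (3 low, 3 high)."""
    samples = pd.DataFrame(
        {"ef_percent": [30, 35, 25, 60, 55, 65],
         "ef_class": ["low"] * 3 + ["high"] * 3},
        index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
    )
    expr = pd.DataFrame(
        [
            [np.log2(1.3)] * 3 + [0.0] * 3,            # fold change exactly 1.3
            [0.5, 0.5, 0.5, 0.5, 0.5, 0.5],            # identical means
            [-1.0, -1.0, -1.0, 0.0, 0.0, 0.0],         # fold change 0.5
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],            # SAM enumeration toy
        ],
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
        columns=samples.index,
        dtype=float,
    )
    return expr, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
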