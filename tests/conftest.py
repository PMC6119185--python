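import pandas as pd
import pytest

import sennet


@pytest.fixture(scope="session")
def default_bundle():
    """The default desk-scale study bundle (2,000 genes, 12 time points,
    3 replicates, heavy-tailed module sizes, seed 42)."""
    cfg = sennet.SynthConfig()
    expr, mir_expr, tf_edges, mir_edges, truth = sennet.generate_dataset(cfg)
    return cfg, expr, mir_expr, tf_edges, mir_edges, truth


@pytest.fixture(scope="session")
def default_network(default_bundle):
    """Co-expression network built from the default bundle."""
    _, expr, *_ = default_bundle
    return sennet.build_network(expr)


@pytest.fixture(scope="session")
def small_bundle():
    """A fast small bundle for plumbing tests."""
    cfg = sennet.SynthConfig(
        n_genes=120,
        module_sizes=[40, 30, 20],
        n_tfs=3,
        targets_per_tf=8,
        n_mirs=2,
        targets_per_mir=5,
        split_time=[5],
        seed=7,
    )
    return cfg, *sennet.generate_dataset(cfg)


@pytest.fixture()
def toy_dataset():
    """2 genes x 2 time points x 3 replicates with hand-checkable values."""
    values = pd.DataFrame(
        {
            "T00R0": [1.0, 5.0],
            "T00R1": [1.2, 5.0],
            "T00R2": [0.8, 5.0],
            "T01R0": [3.1, 5.0],
            "T01R1": [2.9, 5.0],
            "T01R2": [3.0, 5.0],
        },
        index=["shifted", "flat"],
    )
    samples = pd.DataFrame(
        {"time": [0, 0, 0, 1, 1, 1], "replicate": [0, 1, 2, 0, 1, 2]},
        index=pd.Index(values.columns, name="sample"),
    )
    return sennet.ExpressionDataset(values=values, samples=samples)
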