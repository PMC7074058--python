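import numpy as np
import pytest

from taxodelim.simulate import (
    SimulationConfig,
    planted_metadata,
    planted_two_genus_config,
    simulate_clade,
)


@pytest.fixture(scope="session")
def planted_clade():
    """The documented two-genus fixture clade (15 genomes, 200 genes)."""
    return simulate_clade(planted_two_genus_config(seed=1))


@pytest.fixture(scope="session")
def planted_results(planted_clade):
    """Measures and partitions of the planted clade (computed once)."""
    from taxodelim.pipeline import run_clade_pipeline

    return run_clade_pipeline(planted_clade, meta=planted_metadata())


@pytest.fixture(scope="session")
def small_clade():
    """Cheap three-leaf clade for mechanics tests (no gene turnover)."""
    cfg = SimulationConfig(
        seed=7,
        n_genes=12,
        tree="((A:0.01,B:0.01):0.05,C:0.06);",
    )
    return simulate_clade(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
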