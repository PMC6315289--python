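import numpy as np
import pytest

from trajkl.datatypes import CellRecord, CountMatrix, RunConfig
from trajkl.simulate import SimConfig, simulate_expression


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_matrix():
    return CountMatrix(["g1", "g2"], ["c1", "c2"], np.array([[100.0, 200.0], [10.0, 20.0]]))


@pytest.fixture
def tiny_cells():
    return [
        CellRecord("c1", 0.0, 7_000_000),
        CellRecord("c2", 48.0, 8_000_000),
    ]


def make_cells(times, ids=None, min_reads=7_000_000):
    if ids is None:
        ids = [f"c{i}" for i in range(len(times))]
    return [CellRecord(cid, float(t), min_reads + i) for i, (cid, t) in enumerate(zip(ids, times))]


@pytest.fixture(scope="session")
def small_sim():
    """Shared small strong-signal simulation (30 cells, 30 genes)."""
    cfg = SimConfig(seed=7, n_cells_per_group=10, n_down=10, n_up=10, n_flat=10)
    return simulate_expression(cfg)


@pytest.fixture
def fast_config():
    return RunConfig(
        kl_direction="symmetrized",
        n_analysis_genes=20,
        mcmc_chains=1,
        mcmc_warmup=100,
        mcmc_draws=100,
        n_permutations=99,
        seed=11,
    )
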