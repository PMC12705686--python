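import pytest

from replidyn import simdata
from replidyn.grid import BinGrid


@pytest.fixture(scope="session")
def reference_rt():
    """Domain-structured reference RT profile: 2000 40-kb bins, 40 domains."""
    return simdata.make_reference_rt(2000, 40, seed=1)


@pytest.fixture(scope="session")
def g1_pool(reference_rt):
    """Summed counts of 20 simulated G1 control cells (haploid baseline)."""
    counts, _ = simdata.simulate_g1_panel(
        reference_rt, n_cells=20, seed=9, ploidy=1
    )
    return counts.sum(axis=0)


@pytest.fixture
def small_grid():
    return BinGrid.from_chrom_sizes({"chr1": 400_000, "chr2": 200_000}, 40_000)
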