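import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from statewitch import (
    BinGrid,
    GeneModel,
    GenomicInterval,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def grid():
    return BinGrid({"chr1": 10_000, "chr2": 6_000}, bin_size=200)


@pytest.fixture(scope="session")
def genes():
    """Three genes on chr1 (two strands) and one on chr2."""
    def mk(gid, chrom, start, end, strand, exons):
        tx = GenomicInterval(chrom, start, end, strand)
        blocks = [GenomicInterval(chrom, a, b, strand) for a, b in exons]
        return GeneModel(gid, gid, tx, blocks)

    return [
        mk("GA", "chr1", 2000, 6000, "+", [(2000, 2500), (5000, 6000)]),
        mk("GB", "chr1", 7000, 9000, "-", [(7000, 9000)]),
        mk("GC", "chr2", 1000, 3000, "+", [(1000, 3000)]),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort at reduced size, shared across tests."""
    cfg = SimulationConfig(n_bins=4000, n_patients=6, n_genes=120, seed=5)
    return simulate_cohort(cfg)
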