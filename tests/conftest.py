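import pytest
from hypothesis import HealthCheck, settings

from grip.core import GeneModel, InsertionSite, Strand
from grip.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_genes():
    """Two forward genes on chr1 with well-separated windows."""
    return [
        GeneModel("gA", "ALPHA", "chr1", Strand.FORWARD, 100_000, 110_000),
        GeneModel("gB", "BETA", "chr1", Strand.REVERSE, 300_000, 320_000),
    ]


@pytest.fixture
def make_insertion():
    def _make(chrom="chr1", pos=0, strand="+", copies=1, id=None):
        return InsertionSite(chrom, pos, Strand.parse(strand), copies, id)

    return _make


@pytest.fixture(scope="session")
def hot_dataset():
    """One simulated screen with 10 designated hot genes of weight 20."""
    config = SimulationConfig(
        seed=11, hot_genes={f"g{i:04d}": 20.0 for i in range(10)}
    )
    genes, peaks, insertions, truth = simulate_dataset(config)
    return config, genes, peaks, insertions, truth
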