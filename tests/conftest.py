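import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from circscape.genome_io import GeneModel
from circscape.synthetic_data import SimulationConfig, generate


@pytest.fixture
def toy_gene() -> GeneModel:
    """Three-exon + strand gene: exons [100,200), [300,400), [500,600)."""
    return GeneModel("g1", "chr1", "+", [(100, 200), (300, 400), (500, 600)])


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle, shared by recovery tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate(SimulationConfig(seed=11), outdir)


@pytest.fixture(scope="session")
def flat_bundle(tmp_path_factory):
    """Bundle with NO planted repeat/methylation enrichment."""
    outdir = tmp_path_factory.mktemp("flat_bundle")
    cfg = SimulationConfig(
        seed=11,
        repeat_fraction_circ=0.15,
        methylation_circ=0.25,
    )
    return generate(cfg, outdir)
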