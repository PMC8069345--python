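import pytest

from methyltsg.config import PipelineConfig
from methyltsg.pipeline import run_all
from methyltsg.sixmer import make_synthetic_model


@pytest.fixture(scope="session")
def model():
    """Full synthetic pore model: sd 2 pA, methylation shift 4 pA (2 sigma)."""
    return make_synthetic_model(sd=2.0, delta=4.0, seed=0)


@pytest.fixture(scope="session")
def default_result():
    """One full pipeline replicate at the default study conditions."""
    return run_all(PipelineConfig(seed=11))


@pytest.fixture()
def small_config():
    """Reduced problem size for tests that run several replicates."""
    cfg = PipelineConfig(seed=5)
    cfg.simulator.n_genes = 24
    cfg.simulator.chrom_length = 150_000
    cfg.simulator.cpg_density = 0.004
    cfg.simulator.n_tumor = 40
    cfg.simulator.n_normal = 15
    return cfg
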