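import numpy as np
import pytest

from circsponge import PipelineConfig, SimConfig, run_pipeline
from circsponge.io import ExonModel


@pytest.fixture(scope="session")
def pipeline_result():
    """One full synthetic run shared by the suite (fixed seed)."""
    return run_pipeline(PipelineConfig(seed=7))


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_gene():
    """A 5-exon plus-strand gene on a deterministic 4 kb chromosome."""
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=4000)])
    exons = ((200, 400), (600, 800), (1000, 1300), (1500, 1700), (2000, 2400))
    model = ExonModel("GENEX", "TXX", "chrT", "+", exons)
    return {"genome": {"chrT": seq}, "model": model}


@pytest.fixture()
def toy_gene_minus(toy_gene):
    model = toy_gene["model"]
    minus = ExonModel("GENEY", "TXY", "chrT", "-", model.exons)
    return {"genome": toy_gene["genome"], "model": minus}
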