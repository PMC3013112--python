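import numpy as np
import pytest
from hypothesis import settings

from kbweight import io

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20101231)


@pytest.fixture(scope="session")
def fixture_genome(tmp_path_factory):
    """Small synthetic input bundle shared across tests."""
    out = tmp_path_factory.mktemp("genome")
    paths = io.generate_fixture_genome(
        out, n_snps=2000, n_genes=100, n_pathways=20, planted_signals=3,
        rng_seed=42,
    )
    return paths


@pytest.fixture(scope="session")
def pipeline_inputs(fixture_genome):
    from kbweight import iterate

    return iterate.PipelineInputs(
        assoc=io.read_assoc(fixture_genome["assoc"]),
        annotations=io.read_annotation(fixture_genome["annotation"]),
        pathways=io.read_gmt(fixture_genome["pathways"]),
        ppi_edges=io.read_ppi(fixture_genome["ppi"]),
        ld_proxies=io.read_ld_proxies(fixture_genome["ld"]),
    )
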