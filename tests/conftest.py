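import pytest

from circarch.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_host_genes=12, n_background_genes=30, seed=7)


@pytest.fixture(scope="session")
def bundle(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(small_config, outdir=str(outdir))


@pytest.fixture(scope="session")
def genes_by_id(bundle):
    return {g.gene_id: g for g in bundle.genes}
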