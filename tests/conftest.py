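import pytest

from bayesase import SamplerConfig, simfix


@pytest.fixture(scope="session")
def toy_fixture(tmp_path_factory):
    """Miniature end-to-end data set (FASTA, VCFs, SAMs, BED) with known truth."""
    out = tmp_path_factory.mktemp("toyfix")
    return simfix.make_toy_fixture(seed=11, out_dir=out)


@pytest.fixture
def fast_config():
    """Small sampler budget for tests that only need coarse posteriors."""
    return SamplerConfig(chains=2, iterations=800, warmup=200, seed=7)
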