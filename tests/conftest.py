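import pytest

from allelobis import fixtures


@pytest.fixture(scope="session")
def region():
    """The bundled 444-nt promoter-like reference (6 CpG + 5 CCWGG, G/A SNP)."""
    return fixtures.promoter_region()


@pytest.fixture(scope="session")
def sites(region):
    return region.sites()


@pytest.fixture(scope="session")
def gdna_datasets():
    """All five zero-noise genomic clone datasets keyed by sample name."""
    return {name: fixtures.load_sample(name) for name in fixtures.GDNA_SAMPLES}


@pytest.fixture(scope="session")
def cdna_dataset():
    return fixtures.load_sample("LNCaP_cDNA")
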