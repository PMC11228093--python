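import pytest

from cosegscan.synthetic_data import table1_fixture
from cosegscan.variant_io import read_group_manifest, read_vcf


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The published worked-example bundle with 20 decoy records."""
    return table1_fixture(tmp_path_factory.mktemp("fixture"), n_decoys=20)


@pytest.fixture(scope="session")
def fixture_matrix(fixture_bundle):
    return read_vcf(fixture_bundle.vcf)


@pytest.fixture(scope="session")
def fixture_groups(fixture_bundle, fixture_matrix):
    return read_group_manifest(fixture_bundle.manifest, fixture_matrix.samples)
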