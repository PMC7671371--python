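import pytest
from hypothesis import settings

from pepdigest import EnzymeCatalog, default_catalog

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog() -> EnzymeCatalog:
    return default_catalog()


@pytest.fixture(scope="session")
def trypsin(catalog):
    return catalog.get("trypsin")


@pytest.fixture(scope="session")
def hydroxylamine(catalog):
    return catalog.get("hydroxylamine")


@pytest.fixture(scope="session")
def staph_peptidase(catalog):
    return catalog.get("staphylococcal-peptidase-i")


@pytest.fixture(scope="session")
def thrombin_sg(catalog):
    return catalog.get("thrombin-sg")


@pytest.fixture
def two_record_fasta(tmp_path):
    path = tmp_path / "input.fasta"
    path.write_text(">prot1 first test protein\nAEERT\n>prot2\nLVPRGSNG\n")
    return path
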