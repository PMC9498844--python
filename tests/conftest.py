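import pytest

from lcr22map import haplotype_model as hm


@pytest.fixture(scope="session")
def catalog() -> hm.FamilyCatalog:
    return hm.build_family_catalog()


@pytest.fixture(scope="session")
def arch(catalog) -> hm.Architecture:
    return catalog.arch


@pytest.fixture(scope="session")
def father(catalog):
    return catalog.individuals["father"]


@pytest.fixture(scope="session")
def mother(catalog):
    return catalog.individuals["mother"]


@pytest.fixture(scope="session")
def proband(catalog):
    return catalog.individuals["proband"]
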