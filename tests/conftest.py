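import pytest
from hypothesis import HealthCheck, settings

from ecointeractions import (
    Dataset,
    EvidenceSource,
    Locality,
    OrganismRole,
    TaxonConcept,
    VocabularySet,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def vocabs() -> VocabularySet:
    return VocabularySet.defaults()


@pytest.fixture()
def empty_dataset(vocabs) -> Dataset:
    return Dataset(vocabularies=vocabs)


def make_louse() -> OrganismRole:
    return OrganismRole(
        taxon=TaxonConcept(
            name="Columbicola columbae",
            classification_path=(
                "Animalia", "Arthropoda", "Insecta", "Phthiraptera", "Columbicola columbae",
            ),
        ),
        establishment_status="Native",
        organism_part="wings",
    )


def make_host() -> OrganismRole:
    return OrganismRole(
        taxon=TaxonConcept(
            name="Columba livia",
            classification_path=("Animalia", "Chordata", "Aves", "Columba livia"),
        ),
        establishment_status="Native",
    )


@pytest.fixture()
def louse_dataset(vocabs) -> Dataset:
    """One louse-on-pigeon record, typed with the child term 'ectoparasite of'."""
    dataset = Dataset(vocabularies=vocabs)
    dataset.create_record(
        make_louse(),
        make_host(),
        "ectoparasite of",
        evidence=[EvidenceSource(kind="reference", citation="Clay (1951)")],
        locality=Locality(name="London, United Kingdom", latitude=51.5, longitude=-0.1),
    )
    return dataset
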