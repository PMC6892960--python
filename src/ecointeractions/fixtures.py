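"""Seeded synthetic interaction datasets for tests, demos and benchmarks.

Two archetypes emulate the shapes of classic interaction databases:

* ``herbivory`` — phasmid and lepidopteran herbivores on host plants
  ("eats"), including a cluster of records in the style of *Carausius
  morosus* in San Diego: an introduced stick insect found feeding on
  plants that are themselves introduced;
* ``parasitism`` — chewing/sucking lice on bird and mammal hosts
  ("ectoparasite of"), with organism parts such as "wings", "head and
  neck" or "rump" recorded verbatim;
* ``mixed`` — an even blend of both.

Generation is fully deterministic for a given spec: sampling is driven by
one seeded RNG and record UUIDs are name-based (UUIDv5 over seed and row
index), so two runs produce byte-identical datasets.  The accompanying
:class:`GeneratorTally` keeps exact counts per status/type while
generating, for use as an independent oracle against facet counts.

Taxon names are decorative plausibilities, not authoritative data.
"""

from __future__ import annotations

import random
import uuid as _uuid
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

from .datamodel import (
    Dataset,
    EvidenceSource,
    Locality,
    OrganismRole,
    TaxonConcept,
)
from .errors import FixtureSpecError
from .vocabulary import VocabularySet

#: Namespace for name-based fixture UUIDs (itself a fixed v5 of the DNS
#: namespace, so fixtures are reproducible everywhere).
FIXTURE_NAMESPACE = _uuid.uuid5(_uuid.NAMESPACE_DNS, "ecointeractions.fixtures")

ARCHETYPES = ("herbivory", "parasitism", "mixed")

DEFAULT_STATUS_MIX: Mapping[str, float] = {
    "Native": 0.55,
    "Introduced": 0.20,
    "Naturalised": 0.10,
    "Invasive": 0.05,
    "Managed": 0.05,
    "Captivity": 0.05,
}

_HERBIVORES = (
    ("Timema californicum", ("Animalia", "Arthropoda", "Insecta", "Phasmida")),
    ("Extatosoma tiaratum", ("Animalia", "Arthropoda", "Insecta", "Phasmida")),
    ("Medauroidea extradentata", ("Animalia", "Arthropoda", "Insecta", "Phasmida")),
    ("Vanessa cardui", ("Animalia", "Arthropoda", "Insecta", "Lepidoptera")),
    ("Operophtera brumata", ("Animalia", "Arthropoda", "Insecta", "Lepidoptera")),
    ("Choristoneura fumiferana", ("Animalia", "Arthropoda", "Insecta", "Lepidoptera")),
)
_CARAUSIUS = ("Carausius morosus", ("Animalia", "Arthropoda", "Insecta", "Phasmida"))

_PLANTS = (
    ("Quercus agrifolia", ("Plantae", "Tracheophyta", "Magnoliopsida")),
    ("Salvia apiana", ("Plantae", "Tracheophyta", "Magnoliopsida")),
    ("Ceanothus spinosus", ("Plantae", "Tracheophyta", "Magnoliopsida")),
    ("Pinus ponderosa", ("Plantae", "Tracheophyta", "Pinopsida")),
)
_INTRODUCED_PLANTS = (
    ("Rosa sp.", ("Plantae", "Tracheophyta", "Magnoliopsida")),
    ("Hedera helix", ("Plantae", "Tracheophyta", "Magnoliopsida")),
    ("Eucalyptus globulus", ("Plantae", "Tracheophyta", "Magnoliopsida")),
    ("Pittosporum tobira", ("Plantae", "Tracheophyta", "Magnoliopsida")),
)

_LICE = (
    ("Columbicola columbae", ("Animalia", "Arthropoda", "Insecta", "Phthiraptera")),
    ("Craspedorrhynchus platystomus", ("Animalia", "Arthropoda", "Insecta", "Phthiraptera")),
    ("Pediculus schaeffi", ("Animalia", "Arthropoda", "Insecta", "Phthiraptera")),
    ("Trichodectes canis", ("Animalia", "Arthropoda", "Insecta", "Phthiraptera")),
)
_HOSTS = (
    ("Columba livia", ("Animalia", "Chordata", "Aves")),
    ("Aquila chrysaetos", ("Animalia", "Chordata", "Aves")),
    ("Passer domesticus", ("Animalia", "Chordata", "Aves")),
    ("Canis lupus", ("Animalia", "Chordata", "Mammalia")),
    ("Pan troglodytes", ("Animalia", "Chordata", "Mammalia")),
)

_HOST_PARTS = ("wings", "head and neck", "rump")
_PLANT_PARTS = ("leaves", "flowers", "tubers")

_LOCALITIES = (
    ("San Diego, California", 32.7157, -117.1611),
    ("Tamil Nadu, India", 11.1271, 78.6569),
    ("Chiang Mai, Thailand", 18.7883, 98.9853),
    ("Quito, Ecuador", -0.1807, -78.4678),
    ("London, United Kingdom", 51.5072, -0.1276),
)

_CITATIONS = (
    "Grey (1833) Revision of the Phasmidae",
    "Clay (1951) The louse fauna of raptorial birds",
    "Robinson et al. (2010) Hostplant catalogue",
    "Dupont (2016) Field notes, San Diego survey",
)
_CATALOGUE_IDS = ("NHMUK 010305771", "NHMUK 013442108", "USNM 1456220")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``status_mix`` is the per-side sampling distribution over organism
    establishment statuses (must sum to 1); ``captive_fraction`` is the
    probability that a record's interaction status is one of the three
    captivity values rather than "recorded in the wild";
    ``part_fraction`` the probability a record carries an organism part;
    ``importance_fraction`` the probability it carries an importance
    value; ``cluster_fraction`` the share of herbivory records drawn from
    the introduced-herbivore-on-introduced-plant cluster;
    ``locality_fraction`` the probability a record has a locality.
    """

    seed: int = 0
    n_records: int = 100
    archetype: str = "mixed"
    status_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_MIX)
    )
    captive_fraction: float = 0.2
    part_fraction: float = 0.3
    importance_fraction: float = 0.15
    cluster_fraction: float = 0.15
    locality_fraction: float = 0.6

    def validate(self, vocabularies: VocabularySet) -> None:
        if self.archetype not in ARCHETYPES:
            raise FixtureSpecError(
                f"archetype must be one of {ARCHETYPES}, got {self.archetype!r}"
            )
        if self.n_records < 0:
            raise FixtureSpecError("n_records must be >= 0")
        total = sum(self.status_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise FixtureSpecError(f"status_mix must sum to 1, got {total}")
        for label, p in self.status_mix.items():
            if vocabularies.organism_status.canonical(label) is None:
                raise FixtureSpecError(f"status_mix: unknown status {label!r}")
            if p < 0:
                raise FixtureSpecError(f"status_mix: negative probability for {label!r}")
        for name in (
            "captive_fraction",
            "part_fraction",
            "importance_fraction",
            "cluster_fraction",
            "locality_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise FixtureSpecError(f"{name} must be in [0, 1], got {value}")


@dataclass
class GeneratorTally:
    """Exact bookkeeping kept while generating, for oracle use in tests.

    ``native_native_uuids`` lists the records in which *neither* role has
    establishment status "Introduced" — exactly the set an
    exclude-Introduced-on-both-sides query should return.
    """

    interaction_type: Counter = field(default_factory=Counter)
    subject_status: Counter = field(default_factory=Counter)
    object_status: Counter = field(default_factory=Counter)
    interaction_status: Counter = field(default_factory=Counter)
    importance: Counter = field(default_factory=Counter)
    native_native_uuids: list[str] = field(default_factory=list)


def _weighted_choice(rng: random.Random, mix: Mapping[str, float]) -> str:
    labels = list(mix)
    return rng.choices(labels, weights=[mix[l] for l in labels], k=1)[0]


def _taxon(entry: tuple[str, tuple[str, ...]]) -> TaxonConcept:
    name, ancestors = entry
    return TaxonConcept(name=name, classification_path=ancestors + (name,))


def generate_fixture(
    spec: FixtureSpec, vocabularies: VocabularySet | None = None
) -> tuple[Dataset, GeneratorTally]:
    """Generate a deterministic synthetic dataset plus its exact tally."""
    vocabs = vocabularies or VocabularySet.defaults()
    spec.validate(vocabs)
    rng = random.Random(spec.seed)
    dataset = Dataset(
        vocabularies=vocabs,
        metadata={
            "source": f"synthetic fixture (seed={spec.seed}, archetype={spec.archetype})",
            "licence": "CC0",
        },
    )
    tally = GeneratorTally()
    status_labels = {
        l: vocabs.organism_status.canonical(l) for l in spec.status_mix
    }
    wild_label, *captive_labels = vocabs.interaction_status.labels

    for i in range(spec.n_records):
        if spec.archetype == "mixed":
            kind = "herbivory" if rng.random() < 0.5 else "parasitism"
        else:
            kind = spec.archetype

        subject_part = object_part = None
        if kind == "herbivory":
            interaction_type = "eats"
            if rng.random() < spec.cluster_fraction:
                # introduced herbivore on introduced plant, Carausius-style
                subject = OrganismRole(
                    taxon=_taxon(_CARAUSIUS), establishment_status="Introduced"
                )
                obj_taxon = _taxon(rng.choice(_INTRODUCED_PLANTS))
                obj_status = "Introduced"
            else:
                subject = OrganismRole(
                    taxon=_taxon(rng.choice(_HERBIVORES)),
                    establishment_status=status_labels[
                        _weighted_choice(rng, spec.status_mix)
                    ],
                )
                obj_taxon = _taxon(rng.choice(_PLANTS + _INTRODUCED_PLANTS))
                obj_status = status_labels[_weighted_choice(rng, spec.status_mix)]
            if rng.random() < spec.part_fraction:
                object_part = rng.choice(_PLANT_PARTS)
            obj = OrganismRole(
                taxon=obj_taxon, establishment_status=obj_status, organism_part=object_part
            )
        else:
            interaction_type = "ectoparasite of"
            if rng.random() < spec.part_fraction:
                subject_part = rng.choice(_HOST_PARTS)
            subject = OrganismRole(
                taxon=_taxon(rng.choice(_LICE)),
                establishment_status=status_labels[
                    _weighted_choice(rng, spec.status_mix)
                ],
                organism_part=subject_part,
            )
            obj = OrganismRole(
                taxon=_taxon(rng.choice(_HOSTS)),
                establishment_status=status_labels[
                    _weighted_choice(rng, spec.status_mix)
                ],
            )

        if rng.random() < spec.captive_fraction:
            interaction_status = rng.choice(captive_labels)
        else:
            interaction_status = wild_label
        importance = None
        if rng.random() < spec.importance_fraction:
            importance = rng.choice(vocabs.importance.labels)

        evidence = [
            EvidenceSource(kind="reference", citation=rng.choice(_CITATIONS))
        ]
        if rng.random() < 0.3:
            evidence.append(
                EvidenceSource(
                    kind=rng.choice(("specimen", "observation")),
                    citation=rng.choice(_CATALOGUE_IDS),
                )
            )
        rng.shuffle(evidence)

        locality = None
        if rng.random() < spec.locality_fraction:
            name, lat, lon = rng.choice(_LOCALITIES)
            if rng.random() < 0.25:
                locality = Locality(name=name)  # name-only record
            else:
                locality = Locality(name=name, latitude=lat, longitude=lon)

        record = dataset.create_record(
            subject,
            obj,
            interaction_type,
            interaction_status=interaction_status,
            importance=importance,
            evidence=evidence,
            locality=locality,
            uuid=str(_uuid.uuid5(FIXTURE_NAMESPACE, f"{spec.seed}/{i}")),
        )
        tally.interaction_type[record.interaction_type] += 1
        tally.subject_status[record.subject.establishment_status] += 1
        tally.object_status[record.object.establishment_status] += 1
        tally.interaction_status[record.interaction_status] += 1
        if record.importance is not None:
            tally.importance[record.importance] += 1
        if (
            record.subject.establishment_status != "Introduced"
            and record.object.establishment_status != "Introduced"
        ):
            tally.native_native_uuids.append(record.uuid)
    return dataset, tally
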