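"""Domain types for documented species interactions.

An :class:`InteractionRecord` states that one organism (the *subject*, e.g.
a chewing louse) stands in a typed relation (e.g. "ectoparasite of") to
another (the *object*, e.g. its bird host), together with the evidence for
the claim (a reference, a museum specimen or an observation), an optional
locality, controlled-vocabulary statuses and a persistent UUID.  The UUID is
the record's provenance anchor: aggregators keep it, so corrections can flow
back to the source dataset.

Constructors are deliberately permissive — every invariant is checked by
:func:`validate_record`, which returns :class:`Violation` objects rather
than raising, so a curator can see all problems with a record at once.
"""

from __future__ import annotations

import uuid as _uuid
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

from .errors import DuplicateUUIDError
from .vocabulary import UNKNOWN, InteractionTypeVocabulary, VocabularySet

EVIDENCE_KINDS = ("reference", "specimen", "observation")


@dataclass(frozen=True)
class TaxonConcept:
    """A taxon as used by one record: a name, optionally with context.

    ``classification_path`` is the ordered ancestor chain from root down to
    (and including) the taxon itself.  It is stored per record side rather
    than in one global tree because different sources legitimately follow
    different classifications of the same group.
    """

    name: str
    rank: str | None = None
    classification_path: tuple[str, ...] = ()
    external_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "classification_path", tuple(self.classification_path))


@dataclass(frozen=True)
class OrganismRole:
    """A taxon playing one side of an interaction.

    ``organism_part`` is verbatim free text from the source ("wings",
    "head and neck", "flowers"); no normalisation is applied, because
    sources predate any shared anatomy vocabulary.
    """

    taxon: TaxonConcept
    establishment_status: str = UNKNOWN
    organism_part: str | None = None


@dataclass(frozen=True)
class EvidenceSource:
    """What backs the record: a reference, a specimen or an observation."""

    kind: str
    citation: str
    identifier: str | None = None


@dataclass(frozen=True)
class Locality:
    """A named place and/or a WGS84 coordinate pair (decimal degrees)."""

    name: str | None = None
    latitude: float | None = None
    longitude: float | None = None


@dataclass(frozen=True)
class InteractionRecord:
    uuid: str
    subject: OrganismRole
    object: OrganismRole
    interaction_type: str
    interaction_status: str = UNKNOWN
    importance: str | None = None
    evidence: tuple[EvidenceSource, ...] = ()
    locality: Locality | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "evidence", tuple(self.evidence))


@dataclass(frozen=True)
class Violation:
    """One broken rule: which field, what value, which rule."""

    field: str
    value: object
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r}: {self.rule}"


def _valid_uuid(value: str) -> bool:
    try:
        _uuid.UUID(str(value))
        return True
    except (ValueError, AttributeError, TypeError):
        return False


def _check_role(side: str, role: OrganismRole, vocabs: VocabularySet) -> list[Violation]:
    out: list[Violation] = []
    name = role.taxon.name or ""
    if not name.strip():
        out.append(Violation(f"{side}.taxon.name", name, "taxon name must be non-empty"))
    path = role.taxon.classification_path
    if path and name.strip() and path[-1] != name:
        out.append(
            Violation(
                f"{side}.taxon.classification_path",
                path,
                "last element of classification_path must equal the taxon name",
            )
        )
    status = role.establishment_status
    if not isinstance(status, str) or vocabs.organism_status.canonical(status) is None:
        out.append(
            Violation(
                f"{side}.establishment_status",
                status,
                "not in the organism-status vocabulary (and not 'unknown')",
            )
        )
    return out


def _check_locality(loc: Locality) -> list[Violation]:
    out: list[Violation] = []
    has_lat, has_lon = loc.latitude is not None, loc.longitude is not None
    if has_lat != has_lon:
        out.append(
            Violation(
                "locality",
                (loc.latitude, loc.longitude),
                "latitude and longitude must be both present or both absent",
            )
        )
    if not (loc.name or "").strip() and not (has_lat and has_lon):
        out.append(
            Violation(
                "locality",
                loc,
                "a locality needs a name or a complete coordinate pair",
            )
        )
    if has_lat and not (-90.0 <= float(loc.latitude) <= 90.0):
        out.append(Violation("locality.latitude", loc.latitude, "outside [-90, 90]"))
    if has_lon and not (-180.0 <= float(loc.longitude) <= 180.0):
        out.append(Violation("locality.longitude", loc.longitude, "outside [-180, 180]"))
    return out


def validate_record(record: InteractionRecord, vocabularies: VocabularySet) -> list[Violation]:
    """Check every invariant of *record* against the loaded vocabularies.

    Returns an empty list iff the record is fully valid.  Violations are
    returned, never raised, and every independent problem yields its own
    :class:`Violation` naming the field, the offending value and the rule.
    """
    out: list[Violation] = []
    if not _valid_uuid(record.uuid):
        out.append(Violation("uuid", record.uuid, "not a syntactically valid UUID"))
    out.extend(_check_role("subject", record.subject, vocabularies))
    out.extend(_check_role("object", record.object, vocabularies))
    if (
        not isinstance(record.interaction_type, str)
        or record.interaction_type not in vocabularies.interaction_types
    ):
        out.append(
            Violation(
                "interaction_type",
                record.interaction_type,
                "does not resolve in the interaction-type vocabulary",
            )
        )
    status = record.interaction_status
    if not isinstance(status, str) or vocabularies.interaction_status.canonical(status) is None:
        out.append(
            Violation(
                "interaction_status",
                status,
                "not in the interaction-status vocabulary (and not 'unknown')",
            )
        )
    if record.importance is not None:
        if not isinstance(record.importance, str):
            out.append(
                Violation(
                    "importance",
                    record.importance,
                    "importance is single-valued: one label or absent",
                )
            )
        elif vocabularies.importance.canonical(record.importance) is None:
            out.append(
                Violation(
                    "importance",
                    record.importance,
                    "not in the importance vocabulary",
                )
            )
    for i, ev in enumerate(record.evidence):
        if ev.kind not in EVIDENCE_KINDS:
            out.append(
                Violation(
                    f"evidence[{i}].kind",
                    ev.kind,
                    f"must be one of {EVIDENCE_KINDS}",
                )
            )
        if not (ev.citation or "").strip():
            out.append(
                Violation(f"evidence[{i}].citation", ev.citation, "citation must be non-empty")
            )
    if record.locality is not None:
        out.extend(_check_locality(record.locality))
    return out


def reversed_view(
    record: InteractionRecord, vocabulary: InteractionTypeVocabulary
) -> InteractionRecord:
    """The same interaction read in the opposite direction.

    Subject and object swap (each keeping its own status and organism part)
    and the interaction type is replaced by its inverse, so a record stored
    as (louse, "ectoparasite of", host) can be viewed as (host,
    "ectoparasitized by", louse).  UUID, evidence and locality are
    unchanged; the view is not persisted anywhere.  Applying the view twice
    returns a record equal to the original.
    """
    inverse = vocabulary.inverse_of(record.interaction_type)
    return replace(
        record,
        subject=record.object,
        object=record.subject,
        interaction_type=inverse,
    )


class Dataset:
    """An ordered, UUID-keyed collection of records plus their vocabularies.

    Record order is stable: iteration, export and serialisation all preserve
    insertion order, and no two records may share a UUID.
    """

    def __init__(
        self,
        vocabularies: VocabularySet | None = None,
        metadata: Mapping[str, str] | None = None,
        records: Iterable[InteractionRecord] = (),
    ) -> None:
        self.vocabularies = vocabularies or VocabularySet.defaults()
        self.metadata: dict[str, str] = dict(metadata or {})
        self._records: list[InteractionRecord] = []
        self._by_uuid: dict[str, InteractionRecord] = {}
        for record in records:
            self.add(record)

    @property
    def records(self) -> tuple[InteractionRecord, ...]:
        return tuple(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self._records)

    def __contains__(self, uuid: str) -> bool:
        return uuid in self._by_uuid

    def get(self, uuid: str) -> InteractionRecord:
        try:
            return self._by_uuid[uuid]
        except KeyError:
            raise KeyError(f"no record with uuid {uuid!r}") from None

    def add(self, record: InteractionRecord) -> InteractionRecord:
        """Append *record*, enforcing UUID uniqueness (values kept verbatim)."""
        if record.uuid in self._by_uuid:
            raise DuplicateUUIDError(f"duplicate record uuid {record.uuid!r}")
        self._records.append(record)
        self._by_uuid[record.uuid] = record
        return record

    def create_record(
        self,
        subject: OrganismRole,
        object: OrganismRole,
        interaction_type: str,
        *,
        interaction_status: str = UNKNOWN,
        importance: str | None = None,
        evidence: Iterable[EvidenceSource] = (),
        locality: Locality | None = None,
        uuid: str | None = None,
    ) -> InteractionRecord:
        """Build, register and return a new record.

        The interaction type must resolve in the active vocabulary (the
        error names the offending label).  An explicit ``uuid`` is kept
        verbatim and checked for uniqueness; otherwise a fresh random
        (version-4) UUID is generated.  Vocabulary labels are canonicalised
        to table casing; unset statuses default to the ``unknown`` sentinel.
        """
        vocabs = self.vocabularies
        canonical_type = vocabs.interaction_types.canonical(interaction_type)
        if uuid is None:
            uuid = str(_uuid.uuid4())
        elif uuid in self._by_uuid:
            raise DuplicateUUIDError(f"duplicate record uuid {uuid!r}")

        def _canon_status(role: OrganismRole) -> OrganismRole:
            canon = vocabs.organism_status.canonical(role.establishment_status)
            if canon is not None and canon != role.establishment_status:
                return replace(role, establishment_status=canon)
            return role

        interaction_status = (
            vocabs.interaction_status.canonical(interaction_status) or interaction_status
        )
        if importance is not None:
            importance = vocabs.importance.canonical(importance) or importance
        record = InteractionRecord(
            uuid=uuid,
            subject=_canon_status(subject),
            object=_canon_status(object),
            interaction_type=canonical_type,
            interaction_status=interaction_status,
            importance=importance,
            evidence=tuple(evidence),
            locality=locality,
        )
        return self.add(record)

    def validate(self) -> list[tuple[str, Violation]]:
        """Validate every record; returns ``(uuid, violation)`` pairs."""
        out: list[tuple[str, Violation]] = []
        for record in self._records:
            for violation in validate_record(record, self.vocabularies):
                out.append((record.uuid, violation))
        return out
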