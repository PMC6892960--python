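"""Filtering and faceting over interaction datasets.

The semantics mirror a faceted search page: criteria combine by
conjunction, and facet counts are computed over the filtered result set.
Two retrieval features exploit the vocabulary structure:

* *hierarchy expansion* — a query for "parasite of" also returns records
  typed with child terms such as "ectoparasite of";
* *inverse matching* — a record stored as (louse, "ectoparasite of", host)
  is also found by the opposite-direction query, with role-specific
  criteria evaluated against the reversed view of the record.

Both default on; each can be switched off per query.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .datamodel import Dataset, InteractionRecord, reversed_view
from .errors import CriteriaError, UnknownTermError
from .vocabulary import StatusVocabulary, VocabularySet

SIDES = ("subject", "object", "either")

FACET_FIELDS = (
    "interaction_type",
    "subject_status",
    "object_status",
    "interaction_status",
    "importance",
    "subject_taxon",
    "object_taxon",
)


@dataclass(frozen=True)
class QueryCriteria:
    """Conjunctive faceted-search criteria.

    All fields are optional; an empty criteria object matches everything.
    Status sets match case-insensitively and may include the ``unknown``
    sentinel; ``_in`` and ``_not_in`` sets for the same role must be
    disjoint.  ``taxon_name`` matches a role's exact name or any element
    of its classification path, on the chosen side.
    """

    taxon_name: str | None = None
    taxon_side: str = "either"
    interaction_type: str | None = None
    expand_hierarchy: bool = True
    match_inverse: bool = True
    subject_status_in: frozenset[str] | None = None
    subject_status_not_in: frozenset[str] | None = None
    object_status_in: frozenset[str] | None = None
    object_status_not_in: frozenset[str] | None = None
    interaction_status_in: frozenset[str] | None = None
    importance_in: frozenset[str] | None = None
    locality_name_contains: str | None = None

    def __post_init__(self) -> None:
        for name in (
            "subject_status_in",
            "subject_status_not_in",
            "object_status_in",
            "object_status_not_in",
            "interaction_status_in",
            "importance_in",
        ):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, frozenset(value))


def _resolve_status_set(
    labels: Iterable[str] | None, vocab: StatusVocabulary, what: str
) -> frozenset[str] | None:
    """Lower-cased canonical forms; raises before evaluation on bad labels."""
    if labels is None:
        return None
    out = set()
    for label in labels:
        canon = vocab.canonical(label)
        if canon is None:
            raise UnknownTermError(f"{what}: unknown label {label!r}")
        out.add(canon.lower())
    return frozenset(out)


class _CompiledCriteria:
    """Criteria with all labels resolved and the type set pre-expanded."""

    def __init__(self, criteria: QueryCriteria, vocabs: VocabularySet) -> None:
        if criteria.taxon_side not in SIDES:
            raise CriteriaError(
                f"taxon_side must be one of {SIDES}, got {criteria.taxon_side!r}"
            )
        self.criteria = criteria
        self.subject_in = _resolve_status_set(
            criteria.subject_status_in, vocabs.organism_status, "subject_status_in"
        )
        self.subject_not_in = _resolve_status_set(
            criteria.subject_status_not_in, vocabs.organism_status, "subject_status_not_in"
        )
        self.object_in = _resolve_status_set(
            criteria.object_status_in, vocabs.organism_status, "object_status_in"
        )
        self.object_not_in = _resolve_status_set(
            criteria.object_status_not_in, vocabs.organism_status, "object_status_not_in"
        )
        for a, b, name in (
            (self.subject_in, self.subject_not_in, "subject_status"),
            (self.object_in, self.object_not_in, "object_status"),
        ):
            if a is not None and b is not None and a & b:
                raise CriteriaError(
                    f"{name}: _in and _not_in sets overlap: {sorted(a & b)}"
                )
        self.interaction_status_in = _resolve_status_set(
            criteria.interaction_status_in, vocabs.interaction_status, "interaction_status_in"
        )
        self.importance_in = _resolve_status_set(
            criteria.importance_in, vocabs.importance, "importance_in"
        )
        self.type_set: frozenset[str] | None = None
        if criteria.interaction_type is not None:
            itv = vocabs.interaction_types
            canon = itv.canonical(criteria.interaction_type)  # raises if unknown
            if criteria.expand_hierarchy:
                labels = itv.descendants(canon)
            else:
                labels = {canon}
            self.type_set = frozenset(l.lower() for l in labels)
        self.vocabs = vocabs

    # -- per-view predicate ------------------------------------------------

    def _status_ok(
        self,
        status: str,
        in_set: frozenset[str] | None,
        not_in_set: frozenset[str] | None,
    ) -> bool:
        key = status.strip().lower()
        if in_set is not None and key not in in_set:
            return False
        if not_in_set is not None and key in not_in_set:
            return False
        return True

    def _taxon_ok(self, view: InteractionRecord) -> bool:
        name = self.criteria.taxon_name
        if name is None:
            return True
        roles = {
            "subject": (view.subject,),
            "object": (view.object,),
            "either": (view.subject, view.object),
        }[self.criteria.taxon_side]
        for role in roles:
            if role.taxon.name == name or name in role.taxon.classification_path:
                return True
        return False

    def matches_view(self, view: InteractionRecord) -> bool:
        if self.type_set is not None:
            if view.interaction_type.strip().lower() not in self.type_set:
                return False
        if not self._taxon_ok(view):
            return False
        if not self._status_ok(
            view.subject.establishment_status, self.subject_in, self.subject_not_in
        ):
            return False
        if not self._status_ok(
            view.object.establishment_status, self.object_in, self.object_not_in
        ):
            return False
        if self.interaction_status_in is not None:
            if view.interaction_status.strip().lower() not in self.interaction_status_in:
                return False
        if self.importance_in is not None:
            if (
                view.importance is None
                or view.importance.strip().lower() not in self.importance_in
            ):
                return False
        if self.criteria.locality_name_contains is not None:
            loc = view.locality
            if loc is None or loc.name is None:
                return False
            if self.criteria.locality_name_contains.lower() not in loc.name.lower():
                return False
        return True

    def matches(self, record: InteractionRecord) -> bool:
        if self.matches_view(record):
            return True
        if self.criteria.match_inverse:
            try:
                return self.matches_view(
                    reversed_view(record, self.vocabs.interaction_types)
                )
            except Exception:
                return False
        return False


def filter_records(
    dataset: Dataset, criteria: QueryCriteria | None = None
) -> list[InteractionRecord]:
    """Records satisfying the conjunction of all present criteria.

    Dataset order is preserved.  With ``match_inverse`` on, a record also
    matches when its reversed view (roles swapped, interaction type
    inverted) satisfies the criteria — role-specific conditions are then
    evaluated against the reversed roles.  Unresolvable criterion labels
    raise before any record is examined.
    """
    compiled = _CompiledCriteria(criteria or QueryCriteria(), dataset.vocabularies)
    return [record for record in dataset if compiled.matches(record)]


def _facet_value(record: InteractionRecord, field: str, vocabs: VocabularySet) -> str | None:
    if field == "interaction_type":
        itype = record.interaction_type
        return vocabs.interaction_types.canonical(itype) if itype in vocabs.interaction_types else itype
    if field == "subject_status":
        return vocabs.organism_status.canonical(record.subject.establishment_status) or record.subject.establishment_status
    if field == "object_status":
        return vocabs.organism_status.canonical(record.object.establishment_status) or record.object.establishment_status
    if field == "interaction_status":
        return vocabs.interaction_status.canonical(record.interaction_status) or record.interaction_status
    if field == "importance":
        if record.importance is None:
            return None
        return vocabs.importance.canonical(record.importance) or record.importance
    if field == "subject_taxon":
        return record.subject.taxon.name
    if field == "object_taxon":
        return record.object.taxon.name
    raise UnknownTermError(f"unknown facet field {field!r}; choose from {FACET_FIELDS}")


def facet_counts(
    dataset: Dataset, field: str, criteria: QueryCriteria | None = None
) -> dict[str, int]:
    """Distinct values and counts of *field* over the filtered result set.

    Values with zero count are omitted; the ``unknown`` sentinel appears as
    its own facet value; records without an optional value (``importance``)
    contribute to no bucket.  For always-present single-valued fields the
    counts sum to the result-set size.
    """
    if field not in FACET_FIELDS:
        raise UnknownTermError(
            f"unknown facet field {field!r}; choose from {FACET_FIELDS}"
        )
    counts: dict[str, int] = {}
    for record in filter_records(dataset, criteria):
        value = _facet_value(record, field, dataset.vocabularies)
        if value is None:
            continue
        counts[value] = counts.get(value, 0) + 1
    return counts
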