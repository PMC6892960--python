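"""Controlled vocabularies for species-interaction records.

Two kinds of vocabulary are managed here:

* :class:`StatusVocabulary` — a closed, flat list of ``(label, description)``
  entries.  Three ship with the package: the organism establishment status
  (aligned to the Darwin Core ``establishmentMeans`` property: Native,
  Naturalised, Introduced, Invasive, Captivity, Managed), the wild/captive
  status of the recorded interaction, and the importance of the interaction
  to humans (economic / medical / veterinary values).

* :class:`InteractionTypeVocabulary` — a hierarchical set of relation terms
  ("eats", "parasite of", ...), each carrying a Relations Ontology style IRI
  plus the label and IRI of its inverse ("eaten by" is the inverse of
  "eats").  Terms form a forest via single-parent links, so a query for
  "parasite of" can be expanded to child terms such as "ectoparasite of".

Label matching is case-insensitive on input; canonical (as-loaded) casing is
used on output.  Vocabularies are serialised as UTF-8, LF-terminated TSV
with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .errors import (
    DuplicateTermError,
    HierarchyCycleError,
    InverseSymmetryError,
    MissingInverseError,
    UnknownTermError,
    VocabularyParseError,
)

#: Sentinel accepted wherever a status vocabulary label is expected,
#: for records that have not yet been curated.
UNKNOWN = "unknown"

_STATUS_HEADER = "label\tdescription"
_TERM_HEADER = "label\turi\tinverse_label\tinverse_uri\tparent_label"

#: Built-in vocabulary names -> packaged data file.  "table1".."table3"
#: mirror the order in which the three status vocabularies are conventionally
#: presented; semantic aliases are accepted too.
BUILTIN_STATUS = {
    "table1": ("organism_status", "organism_status.tsv"),
    "organism_status": ("organism_status", "organism_status.tsv"),
    "table2": ("interaction_status", "interaction_status.tsv"),
    "interaction_status": ("interaction_status", "interaction_status.tsv"),
    "table3": ("importance", "importance.tsv"),
    "importance": ("importance", "importance.tsv"),
}

BUILTIN_INTERACTION = {
    "ro-core": "interaction_types.tsv",
    "interaction_types": "interaction_types.tsv",
}


def _data_text(filename: str) -> str:
    return (resources.files("ecointeractions.data") / filename).read_text("utf-8")


@dataclass(frozen=True)
class StatusVocabulary:
    """A closed list of permitted labels with free-text descriptions."""

    name: str
    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, _ in self.entries:
            key = label.strip().lower()
            if not key:
                raise VocabularyParseError(f"{self.name}: empty label")
            if key in seen:
                raise DuplicateTermError(f"{self.name}: duplicate label {label!r}")
            seen.add(key)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.entries)

    def canonical(self, label: str) -> str | None:
        """Return the table-cased form of *label*, or None if absent.

        The :data:`UNKNOWN` sentinel canonicalises to itself.
        """
        key = label.strip().lower()
        if key == UNKNOWN:
            return UNKNOWN
        for candidate, _ in self.entries:
            if candidate.lower() == key:
                return candidate
        return None

    def __contains__(self, label: str) -> bool:
        return self.canonical(label) is not None

    def description(self, label: str) -> str:
        key = label.strip().lower()
        for candidate, desc in self.entries:
            if candidate.lower() == key:
                return desc
        raise UnknownTermError(f"{self.name}: unknown label {label!r}")

    def to_tsv(self) -> str:
        lines = [_STATUS_HEADER]
        lines += [f"{label}\t{desc}" for label, desc in self.entries]
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_bytes(self.to_tsv().encode("utf-8"))
        return path


def load_status_vocabulary(source: str | Path, name: str | None = None) -> StatusVocabulary:
    """Load a status vocabulary from a built-in name or a TSV file.

    Built-ins: ``table1`` / ``organism_status``, ``table2`` /
    ``interaction_status``, ``table3`` / ``importance``.
    """
    if isinstance(source, str) and source in BUILTIN_STATUS:
        builtin_name, filename = BUILTIN_STATUS[source]
        return _parse_status(_data_text(filename), name or builtin_name)
    path = Path(source)
    if not path.exists():
        if isinstance(source, str) and "/" not in source and "\\" not in source:
            raise UnknownTermError(
                f"unknown built-in vocabulary {source!r}; "
                f"choose from {sorted(set(BUILTIN_STATUS))}"
            )
        raise FileNotFoundError(path)
    return _parse_status(path.read_text("utf-8"), name or path.stem)


def _parse_status(text: str, name: str) -> StatusVocabulary:
    lines = text.split("\n")
    if not lines or lines[0].rstrip("\r") != _STATUS_HEADER:
        raise VocabularyParseError(f"{name}: line 1: expected header {_STATUS_HEADER!r}")
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.rstrip("\r")
        if not line:
            continue
        label, _, desc = line.partition("\t")
        if not label.strip():
            raise VocabularyParseError(f"{name}: line {lineno}: empty label")
        if label.strip().lower() in seen:
            raise VocabularyParseError(f"{name}: line {lineno}: duplicate label {label!r}")
        seen.add(label.strip().lower())
        entries.append((label, desc))
    return StatusVocabulary(name=name, entries=tuple(entries))


@dataclass(frozen=True)
class InteractionTypeTerm:
    """One relation term: label + IRI, its inverse, and an optional parent."""

    label: str
    uri: str
    inverse_label: str
    inverse_uri: str
    parent_label: str | None = None

    @property
    def is_self_inverse(self) -> bool:
        return self.inverse_label.strip().lower() == self.label.strip().lower()


class InteractionTypeVocabulary:
    """Hierarchical relation terms with symmetric inverse pairing.

    Invariants, re-verified after every mutation:

    * labels and IRIs are unique (labels case-insensitively);
    * every term's inverse label resolves within the vocabulary (possibly to
      the term itself, for symmetric relations) and the pairing is symmetric;
    * parent links resolve and form a forest (no cycles).
    """

    def __init__(self, terms: Iterable[InteractionTypeTerm] = ()) -> None:
        self._terms: dict[str, InteractionTypeTerm] = {}
        for term in terms:
            self._insert(term)
        self.validate()

    # -- basic access -----------------------------------------------------

    @property
    def terms(self) -> tuple[InteractionTypeTerm, ...]:
        return tuple(self._terms.values())

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[InteractionTypeTerm]:
        return iter(self._terms.values())

    def __contains__(self, label: str) -> bool:
        return label.strip().lower() in self._terms

    def get(self, label: str) -> InteractionTypeTerm:
        try:
            return self._terms[label.strip().lower()]
        except KeyError:
            raise UnknownTermError(f"unknown interaction type {label!r}") from None

    def canonical(self, label: str) -> str:
        return self.get(label).label

    # -- hierarchy and inverses -------------------------------------------

    def children(self, label: str) -> tuple[str, ...]:
        parent = self.get(label).label.lower()
        return tuple(
            t.label
            for t in self._terms.values()
            if t.parent_label is not None and t.parent_label.strip().lower() == parent
        )

    def descendants(self, label: str) -> set[str]:
        """Canonical labels of *label* and all its transitive children."""
        root = self.canonical(label)
        out = {root}
        frontier = [root]
        while frontier:
            nxt: list[str] = []
            for lab in frontier:
                for child in self.children(lab):
                    if child not in out:
                        out.add(child)
                        nxt.append(child)
            frontier = nxt
        return out

    def inverse_of(self, label: str) -> str:
        term = self.get(label)
        return self.get(term.inverse_label).label

    def roots(self) -> tuple[str, ...]:
        return tuple(t.label for t in self._terms.values() if t.parent_label is None)

    # -- mutation ---------------------------------------------------------

    def _insert(self, term: InteractionTypeTerm) -> None:
        parent = term.parent_label.strip() if term.parent_label else None
        term = replace(term, parent_label=parent or None)
        key = term.label.strip().lower()
        if not key:
            raise VocabularyParseError("interaction term with empty label")
        if key in self._terms:
            raise DuplicateTermError(f"duplicate interaction type label {term.label!r}")
        if any(t.uri == term.uri for t in self._terms.values()):
            raise DuplicateTermError(f"duplicate interaction type URI {term.uri!r}")
        self._terms[key] = term

    def add_term(self, term: InteractionTypeTerm) -> "InteractionTypeVocabulary":
        """Add *term*, re-pairing inverses and re-verifying all invariants.

        If the new term's inverse label names an existing term, that term's
        inverse pointers are rewritten so the pairing stays symmetric.  If
        the inverse label names no term (and the term is not self-inverse),
        the partner term is created automatically — label and IRI taken
        from the new term's inverse fields, parent mirrored onto the
        parent's inverse — so the vocabulary never holds a dangling
        inverse.  Returns the vocabulary itself (mutated in place).
        """
        if term.parent_label and term.parent_label.strip().lower() == term.label.strip().lower():
            raise HierarchyCycleError(
                f"term {term.label!r} cannot be its own parent"
            )
        if term.parent_label and term.parent_label.strip().lower() not in self._terms:
            raise UnknownTermError(f"unknown parent term {term.parent_label!r}")
        self._insert(term)
        created_partner = False
        inv_key = term.inverse_label.strip().lower()
        old_partner = self._terms.get(inv_key)
        try:
            partner = old_partner
            if partner is None and not term.is_self_inverse:
                mirror_parent = None
                if term.parent_label is not None:
                    mirror_parent = self.get(term.parent_label).inverse_label
                self._insert(
                    InteractionTypeTerm(
                        label=term.inverse_label,
                        uri=term.inverse_uri,
                        inverse_label=term.label,
                        inverse_uri=term.uri,
                        parent_label=mirror_parent,
                    )
                )
                created_partner = True
            elif partner is not None and partner.label != term.label:
                if (
                    partner.inverse_label.strip().lower() != term.label.strip().lower()
                    or partner.inverse_uri != term.uri
                ):
                    self._terms[inv_key] = replace(
                        partner, inverse_label=term.label, inverse_uri=term.uri
                    )
            self.validate()
        except Exception:
            self._terms.pop(term.label.strip().lower(), None)
            if created_partner:
                self._terms.pop(inv_key, None)
            elif old_partner is not None:
                self._terms[inv_key] = old_partner
            raise
        return self

    # -- consistency ------------------------------------------------------

    def validate(self) -> None:
        """Raise if any structural invariant is broken."""
        for term in self._terms.values():
            inv_key = term.inverse_label.strip().lower()
            partner = self._terms.get(inv_key)
            if partner is None:
                raise MissingInverseError(
                    f"term {term.label!r}: inverse {term.inverse_label!r} "
                    "resolves to no term"
                )
            if partner.inverse_label.strip().lower() != term.label.strip().lower():
                raise InverseSymmetryError(
                    f"asymmetric inverse pair: {term.label!r} -> "
                    f"{term.inverse_label!r} but {partner.label!r} -> "
                    f"{partner.inverse_label!r}"
                )
            if term.parent_label is not None:
                if term.parent_label.strip().lower() not in self._terms:
                    raise UnknownTermError(
                        f"term {term.label!r}: unknown parent {term.parent_label!r}"
                    )
        # cycle detection over parent links
        for term in self._terms.values():
            seen = [term.label]
            cur = term
            while cur.parent_label is not None:
                cur = self._terms[cur.parent_label.strip().lower()]
                if cur.label in seen:
                    cycle = seen[seen.index(cur.label):] + [cur.label]
                    raise HierarchyCycleError(
                        "parent cycle: " + " -> ".join(cycle)
                    )
                seen.append(cur.label)

    def lint(self) -> list[str]:
        """Advisory warnings (not errors).

        Currently flags child terms whose inverse is not a child of the
        parent's inverse — allowed, but often a curation slip.
        """
        warnings = []
        for term in self._terms.values():
            if term.parent_label is None:
                continue
            parent = self.get(term.parent_label)
            inv = self.get(term.inverse_label)
            expected = parent.inverse_label.strip().lower()
            actual = (inv.parent_label or "").strip().lower()
            if not inv.is_self_inverse and actual != expected:
                warnings.append(
                    f"inverse of {term.label!r} ({inv.label!r}) is not a child "
                    f"of the inverse of its parent ({parent.inverse_label!r})"
                )
        return warnings

    # -- serialisation ----------------------------------------------------

    def to_tsv(self) -> str:
        lines = [_TERM_HEADER]
        for t in self._terms.values():
            lines.append(
                f"{t.label}\t{t.uri}\t{t.inverse_label}\t{t.inverse_uri}\t"
                f"{t.parent_label or ''}"
            )
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_bytes(self.to_tsv().encode("utf-8"))
        return path

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionTypeVocabulary):
            return NotImplemented
        return self.terms == other.terms


def load_interaction_vocabulary(source: str | Path) -> InteractionTypeVocabulary:
    """Load the interaction-type vocabulary from a built-in name or TSV file.

    The built-in ``ro-core`` ships a hand-curated set of Relations Ontology
    terms (eats/eaten by, the parasite-of family, pollination, predation,
    hosting) with their inverse pairs and hierarchy.
    """
    if isinstance(source, str) and source in BUILTIN_INTERACTION:
        return _parse_terms(_data_text(BUILTIN_INTERACTION[source]), source)
    path = Path(source)
    if not path.exists():
        if isinstance(source, str) and "/" not in source and "\\" not in source:
            raise UnknownTermError(
                f"unknown built-in vocabulary {source!r}; "
                f"choose from {sorted(set(BUILTIN_INTERACTION))}"
            )
        raise FileNotFoundError(path)
    return _parse_terms(path.read_text("utf-8"), str(path))


def _parse_terms(text: str, name: str) -> InteractionTypeVocabulary:
    lines = text.split("\n")
    if not lines or lines[0].rstrip("\r") != _TERM_HEADER:
        raise VocabularyParseError(f"{name}: line 1: expected header {_TERM_HEADER!r}")
    terms = []
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.rstrip("\r")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise VocabularyParseError(
                f"{name}: line {lineno}: expected 5 tab-separated fields, "
                f"got {len(parts)}"
            )
        label, uri, inverse_label, inverse_uri, parent = parts
        terms.append(
            InteractionTypeTerm(
                label=label,
                uri=uri,
                inverse_label=inverse_label,
                inverse_uri=inverse_uri,
                parent_label=parent or None,
            )
        )
    try:
        return InteractionTypeVocabulary(terms)
    except VocabularyParseError:
        raise
    except Exception as exc:
        raise type(exc)(f"{name}: {exc}") from None


@dataclass(frozen=True)
class VocabularySet:
    """The three status vocabularies plus one interaction-type vocabulary."""

    organism_status: StatusVocabulary
    interaction_status: StatusVocabulary
    importance: StatusVocabulary
    interaction_types: InteractionTypeVocabulary

    @classmethod
    def defaults(cls) -> "VocabularySet":
        return cls(
            organism_status=load_status_vocabulary("table1"),
            interaction_status=load_status_vocabulary("table2"),
            importance=load_status_vocabulary("table3"),
            interaction_types=load_interaction_vocabulary("ro-core"),
        )
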