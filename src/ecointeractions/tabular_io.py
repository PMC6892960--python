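"""Delimited-text import and export of interaction datasets.

Import is mapping-driven: a :class:`ColumnMapping` declares which source
column feeds which record field (or pins a field to a constant), so tables
with arbitrary headers — legacy host-plant lists, louse/host checklists —
can be ingested without reshaping the file first.  Incoming UUIDs are
always preserved verbatim; rows without one get fresh UUIDs.

Export writes the *canonical* column set (below) deterministically: fixed
column order, canonical vocabulary casing, UTF-8, LF line endings.  A
write -> read -> write cycle is byte-identical.

Compound fields use backslash escaping for their separators:

* ``classification_path``: elements joined by ``|``;
* ``evidence``: items joined by ``;``, each item ``kind:citation`` or
  ``kind:citation:identifier``;

with literal ``|``, ``;``, ``:`` and ``\\`` inside values written as
``\\|``, ``\\;``, ``\\:`` and ``\\\\``.
"""

from __future__ import annotations

import csv
import logging
import uuid as _uuid
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .datamodel import (
    Dataset,
    EvidenceSource,
    InteractionRecord,
    Locality,
    OrganismRole,
    TaxonConcept,
    Violation,
    validate_record,
)
from .errors import MappingError, TabularImportError
from .vocabulary import UNKNOWN, VocabularySet

log = logging.getLogger(__name__)

#: Field path -> canonical column name, in canonical column order.
CANONICAL_COLUMNS: tuple[tuple[str, str], ...] = (
    ("uuid", "uuid"),
    ("subject.taxon.name", "subject_taxon_name"),
    ("subject.taxon.rank", "subject_taxon_rank"),
    ("subject.taxon.classification_path", "subject_classification_path"),
    ("subject.taxon.external_id", "subject_taxon_external_id"),
    ("subject.establishment_status", "subject_establishment_status"),
    ("subject.organism_part", "subject_organism_part"),
    ("interaction_type", "interaction_type"),
    ("interaction_status", "interaction_status"),
    ("importance", "importance"),
    ("object.taxon.name", "object_taxon_name"),
    ("object.taxon.rank", "object_taxon_rank"),
    ("object.taxon.classification_path", "object_classification_path"),
    ("object.taxon.external_id", "object_taxon_external_id"),
    ("object.establishment_status", "object_establishment_status"),
    ("object.organism_part", "object_organism_part"),
    ("evidence", "evidence"),
    ("locality.name", "locality_name"),
    ("locality.latitude", "decimal_latitude"),
    ("locality.longitude", "decimal_longitude"),
)

FIELD_PATHS = tuple(path for path, _ in CANONICAL_COLUMNS)
REQUIRED_PATHS = ("subject.taxon.name", "object.taxon.name", "interaction_type")


def _escape(value: str, specials: str) -> str:
    out = []
    for ch in value:
        if ch == "\\" or ch in specials:
            out.append("\\")
        out.append(ch)
    return "".join(out)


def _split_escaped(value: str, sep: str, unescape: bool) -> list[str]:
    """Split on unescaped *sep*; with ``unescape`` the backslash escapes are
    resolved (done only at the innermost nesting level)."""
    out: list[str] = []
    buf: list[str] = []
    i = 0
    while i < len(value):
        ch = value[i]
        if ch == "\\" and i + 1 < len(value):
            if not unescape:
                buf.append("\\")
            buf.append(value[i + 1])
            i += 2
        elif ch == sep:
            out.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(ch)
            i += 1
    out.append("".join(buf))
    return out


def serialize_classification(path: tuple[str, ...]) -> str:
    return "|".join(_escape(p, "|") for p in path)


def parse_classification(text: str) -> tuple[str, ...]:
    if not text:
        return ()
    return tuple(_split_escaped(text, "|", unescape=True))


def serialize_evidence(evidence: tuple[EvidenceSource, ...]) -> str:
    items = []
    for ev in evidence:
        parts = [_escape(ev.kind, ";:"), _escape(ev.citation, ";:")]
        if ev.identifier is not None:
            parts.append(_escape(ev.identifier, ";:"))
        items.append(":".join(parts))
    return ";".join(items)


def parse_evidence(text: str) -> tuple[EvidenceSource, ...]:
    if not text:
        return ()
    out = []
    for item in _split_escaped(text, ";", unescape=False):
        parts = _split_escaped(item, ":", unescape=True)
        kind = parts[0]
        citation = parts[1] if len(parts) > 1 else ""
        identifier = parts[2] if len(parts) > 2 else None
        out.append(EvidenceSource(kind=kind, citation=citation, identifier=identifier))
    return tuple(out)


@dataclass(frozen=True)
class ColumnMapping:
    """Declarative map from record field paths to source columns.

    ``assignments`` maps a field path (``subject.taxon.name``,
    ``locality.latitude``, ...) to a source column name; ``constants`` pins
    a field path to a fixed value applied to every row.  The three paths in
    :data:`REQUIRED_PATHS` must each be covered, and no path may be both
    assigned and constant.
    """

    assignments: Mapping[str, str]
    constants: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for path in list(self.assignments) + list(self.constants):
            if path not in FIELD_PATHS:
                raise MappingError(f"unknown field path {path!r}")
        overlap = set(self.assignments) & set(self.constants)
        if overlap:
            raise MappingError(
                f"field paths both assigned and constant: {sorted(overlap)}"
            )
        missing = [
            p for p in REQUIRED_PATHS if p not in self.assignments and p not in self.constants
        ]
        if missing:
            raise MappingError(f"required field paths not covered: {missing}")

    @classmethod
    def canonical(cls) -> "ColumnMapping":
        """The identity mapping onto the canonical column set."""
        return cls(assignments=dict(CANONICAL_COLUMNS))

    @classmethod
    def from_file(cls, path: str | Path) -> "ColumnMapping":
        """Read a mapping config: one ``field.path = value`` per line.

        A value starting with ``!`` is a constant applied to every row
        (``interaction_type = !eats``); anything else names a source
        column.  Blank lines and ``#`` comments are ignored.
        """
        assignments: dict[str, str] = {}
        constants: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text("utf-8").splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise MappingError(f"{path}: line {lineno}: expected 'field.path = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if value.startswith("!"):
                constants[key] = value[1:].strip()
            else:
                assignments[key] = value
        return cls(assignments=assignments, constants=constants)


@dataclass
class ImportReport:
    """Bookkeeping for one import run."""

    rows_read: int = 0
    records_created: int = 0
    rows_skipped: int = 0
    violations: list[tuple[int, Violation]] = field(default_factory=list)
    violations_by_field: Counter = field(default_factory=Counter)
    warnings: list[str] = field(default_factory=list)

    def record_violation(self, row: int, violation: Violation) -> None:
        self.violations.append((row, violation))
        self.violations_by_field[violation.field] += 1


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _build_record(
    values: dict[str, str], uuid: str, vocabs: VocabularySet
) -> tuple[InteractionRecord, list[Violation]]:
    """Assemble a record from raw field-path values; parse errors become
    violations alongside whatever validate_record finds."""
    problems: list[Violation] = []

    def get(path: str) -> str | None:
        v = values.get(path, "")
        return v if v != "" else None

    def get_float(path: str) -> float | None:
        raw = get(path)
        if raw is None:
            return None
        try:
            return float(raw)
        except ValueError:
            problems.append(Violation(path, raw, "not a decimal number"))
            return None

    def role(side: str) -> OrganismRole:
        status = get(f"{side}.establishment_status") or UNKNOWN
        canon = vocabs.organism_status.canonical(status)
        return OrganismRole(
            taxon=TaxonConcept(
                name=get(f"{side}.taxon.name") or "",
                rank=get(f"{side}.taxon.rank"),
                classification_path=parse_classification(
                    values.get(f"{side}.taxon.classification_path", "")
                ),
                external_id=get(f"{side}.taxon.external_id"),
            ),
            establishment_status=canon if canon is not None else status,
            organism_part=get(f"{side}.organism_part"),
        )

    lat, lon = get_float("locality.latitude"), get_float("locality.longitude")
    loc_name = get("locality.name")
    locality = None
    if loc_name is not None or lat is not None or lon is not None:
        locality = Locality(name=loc_name, latitude=lat, longitude=lon)

    itype = get("interaction_type") or ""
    if itype in vocabs.interaction_types:
        itype = vocabs.interaction_types.canonical(itype)
    istatus = get("interaction_status") or UNKNOWN
    istatus = vocabs.interaction_status.canonical(istatus) or istatus
    importance = get("importance")
    if importance is not None:
        importance = vocabs.importance.canonical(importance) or importance

    record = InteractionRecord(
        uuid=uuid,
        subject=role("subject"),
        object=role("object"),
        interaction_type=itype,
        interaction_status=istatus,
        importance=importance,
        evidence=parse_evidence(values.get("evidence", "")),
        locality=locality,
    )
    return record, problems + validate_record(record, vocabs)


def read_dataset(
    path: str | Path,
    mapping: ColumnMapping | None = None,
    vocabularies: VocabularySet | None = None,
    strict: bool = False,
    delimiter: str | None = None,
) -> tuple[Dataset, ImportReport]:
    """Read a delimited file into a dataset, one record per data row.

    Rows mapping a non-empty ``uuid`` keep it verbatim; others get fresh
    random UUIDs.  In strict mode the first violation aborts with a
    row-numbered :class:`TabularImportError`; otherwise offending rows are
    skipped and tallied in the :class:`ImportReport`.  Row order is
    preserved.
    """
    path = Path(path)
    mapping = mapping or ColumnMapping.canonical()
    vocabs = vocabularies or VocabularySet.defaults()
    dataset = Dataset(vocabularies=vocabs, metadata={"source": str(path)})
    report = ImportReport()

    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=_delimiter_for(path, delimiter))
        try:
            header = next(reader)
        except StopIteration:
            raise TabularImportError(f"{path}: empty file (no header row)") from None
        missing = [c for c in mapping.assignments.values() if c not in header]
        if missing:
            raise MappingError(f"{path}: mapped columns absent from header: {missing}")
        index = {col: header.index(col) for col in mapping.assignments.values()}

        for rowno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            report.rows_read += 1
            values = {
                fieldpath: (row[index[col]] if index[col] < len(row) else "")
                for fieldpath, col in mapping.assignments.items()
            }
            values.update(mapping.constants)

            incoming = values.get("uuid", "").strip()
            uuid = incoming if incoming else str(_uuid.uuid4())
            if uuid in dataset:
                if strict:
                    raise TabularImportError(f"{path}: row {rowno}: duplicate uuid {uuid!r}")
                report.rows_skipped += 1
                report.record_violation(
                    rowno, Violation("uuid", uuid, "duplicate uuid within the file")
                )
                continue

            record, problems = _build_record(values, uuid, vocabs)
            if problems:
                if strict:
                    first = problems[0]
                    raise TabularImportError(
                        f"{path}: row {rowno}: {first.field}={first.value!r}: {first.rule}"
                    )
                report.rows_skipped += 1
                for violation in problems:
                    report.record_violation(rowno, violation)
                continue
            dataset.add(record)
            report.records_created += 1
    return dataset, report


def _serialize_record(record: InteractionRecord, vocabs: VocabularySet) -> list[str]:
    def status(vocab, label: str) -> str:
        return vocab.canonical(label) or label

    loc = record.locality
    itype = record.interaction_type
    if itype in vocabs.interaction_types:
        itype = vocabs.interaction_types.canonical(itype)
    values = {
        "uuid": record.uuid,
        "subject.taxon.name": record.subject.taxon.name,
        "subject.taxon.rank": record.subject.taxon.rank or "",
        "subject.taxon.classification_path": serialize_classification(
            record.subject.taxon.classification_path
        ),
        "subject.taxon.external_id": record.subject.taxon.external_id or "",
        "subject.establishment_status": status(
            vocabs.organism_status, record.subject.establishment_status
        ),
        "subject.organism_part": record.subject.organism_part or "",
        "interaction_type": itype,
        "interaction_status": status(vocabs.interaction_status, record.interaction_status),
        "importance": (
            status(vocabs.importance, record.importance) if record.importance else ""
        ),
        "object.taxon.name": record.object.taxon.name,
        "object.taxon.rank": record.object.taxon.rank or "",
        "object.taxon.classification_path": serialize_classification(
            record.object.taxon.classification_path
        ),
        "object.taxon.external_id": record.object.taxon.external_id or "",
        "object.establishment_status": status(
            vocabs.organism_status, record.object.establishment_status
        ),
        "object.organism_part": record.object.organism_part or "",
        "evidence": serialize_evidence(record.evidence),
        "locality.name": (loc.name or "") if loc else "",
        "locality.latitude": str(loc.latitude) if loc and loc.latitude is not None else "",
        "locality.longitude": str(loc.longitude) if loc and loc.longitude is not None else "",
    }
    return [values[path] for path, _ in CANONICAL_COLUMNS]


def write_dataset(dataset: Dataset, path: str | Path, delimiter: str | None = None) -> Path:
    """Write *dataset* to the canonical column set, byte-deterministically.

    CSV output preserves embedded newlines via quoting; TSV cannot, so
    tabs and newlines inside values are replaced by single spaces (logged
    as a warning).
    """
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    header = [col for _, col in CANONICAL_COLUMNS]
    rows = [_serialize_record(r, dataset.vocabularies) for r in dataset]
    with path.open("w", encoding="utf-8", newline="") as fh:
        if delim == ",":
            writer = csv.writer(fh, delimiter=",", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)
        else:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                clean = []
                for cell in row:
                    if "\t" in cell or "\n" in cell or "\r" in cell:
                        log.warning(
                            "replacing tab/newline with space in TSV cell %r", cell
                        )
                        cell = (
                            cell.replace("\t", " ")
                            .replace("\r\n", " ")
                            .replace("\n", " ")
                            .replace("\r", " ")
                        )
                    clean.append(cell)
                fh.write("\t".join(clean) + "\n")
    return path
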