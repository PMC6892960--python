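"""GloBI-harvestable ``interactions.txt`` export and its self-check.

Global Biotic Interactions (GloBI) aggregates species-interaction datasets
by harvesting simple tab-separated files from source databases.  The export
here writes one header row plus one row per record, in dataset order, with
GloBI-style column names so a downstream template mapping is a rename-only
step.  The column schema is this package's own contract (documented below
and in ``docs/methods.md``), designed to carry every modelled field.

The file is UTF-8, LF-terminated and byte-deterministic for a given
dataset; raw tabs or newlines inside values are replaced by single spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .datamodel import Dataset, InteractionRecord, OrganismRole
from .errors import ExportError
from .vocabulary import UNKNOWN, VocabularySet

#: Canonical column order of the exchange file.
GLOBI_COLUMNS: tuple[str, ...] = (
    "sourceOccurrenceId",
    "sourceTaxonName",
    "sourceBodyPartName",
    "sourceEstablishmentMeans",
    "interactionTypeName",
    "interactionTypeId",
    "targetTaxonName",
    "targetBodyPartName",
    "targetEstablishmentMeans",
    "interactionRecordType",
    "importance",
    "localityName",
    "decimalLatitude",
    "decimalLongitude",
    "referenceCitation",
    "evidenceKind",
)

#: Columns that must be non-empty on every data row of a valid file.
REQUIRED_NONEMPTY = ("sourceTaxonName", "targetTaxonName", "interactionTypeName")


def _clean(value: str) -> str:
    """Tabs and line breaks are structural in this format; flatten them."""
    return (
        value.replace("\t", " ")
        .replace("\r\n", " ")
        .replace("\n", " ")
        .replace("\r", " ")
    )


def _status_or_empty(vocab, label: str) -> str:
    if label == UNKNOWN:
        return ""
    return vocab.canonical(label) or label


def _role_fields(role: OrganismRole, vocabs: VocabularySet) -> tuple[str, str, str]:
    return (
        role.taxon.name,
        role.organism_part or "",
        _status_or_empty(vocabs.organism_status, role.establishment_status),
    )


def _record_row(record: InteractionRecord, vocabs: VocabularySet) -> list[str]:
    try:
        term = vocabs.interaction_types.get(record.interaction_type)
    except Exception:
        raise ExportError(
            f"record {record.uuid}: interaction type "
            f"{record.interaction_type!r} resolves to no term/URI"
        ) from None
    src_name, src_part, src_status = _role_fields(record.subject, vocabs)
    tgt_name, tgt_part, tgt_status = _role_fields(record.object, vocabs)
    reference = next(
        (ev.citation for ev in record.evidence if ev.kind == "reference"), ""
    )
    loc = record.locality
    row = [
        record.uuid,
        src_name,
        src_part,
        src_status,
        term.label,
        term.uri,
        tgt_name,
        tgt_part,
        tgt_status,
        _status_or_empty(vocabs.interaction_status, record.interaction_status),
        record.importance or "",
        (loc.name or "") if loc else "",
        str(loc.latitude) if loc and loc.latitude is not None else "",
        str(loc.longitude) if loc and loc.longitude is not None else "",
        reference,
        ",".join(ev.kind for ev in record.evidence),
    ]
    return [_clean(cell) for cell in row]


def export_globi(dataset: Dataset, path: str | Path) -> Path:
    """Write the dataset as a GloBI-ingestible tab-separated file.

    Exactly one header row, then one row per record in dataset order;
    absent values are empty fields.  Only the first reference-kind evidence
    item is exported to ``referenceCitation``; the full evidence mix is
    summarised in ``evidenceKind`` as a comma-joined list of kinds, keeping
    the file one-row-per-interaction.
    """
    path = Path(path)
    lines = ["\t".join(GLOBI_COLUMNS)]
    for record in dataset:
        lines.append("\t".join(_record_row(record, dataset.vocabularies)))
    path.write_bytes(("\n".join(lines) + "\n").encode("utf-8"))
    return path


@dataclass(frozen=True)
class RuleResult:
    rule: str
    passed: bool
    failures: tuple[tuple[int, str], ...] = ()  # (line number, message)


@dataclass
class GlobiReport:
    """Per-rule outcome of checking an exchange file."""

    results: list[RuleResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.results)

    def rule(self, name: str) -> RuleResult:
        for r in self.results:
            if r.rule == name:
                return r
        raise KeyError(name)


def check_globi_file(path: str | Path) -> GlobiReport:
    """Verify the harvest contract of an ``interactions.txt``-style file.

    Checks: UTF-8 decodability, exact header match, constant per-line field
    count, no raw carriage returns inside the file, and non-empty source
    taxon / target taxon / interaction type on every data row.  Findings
    are reported per rule with line numbers; nothing is raised.
    """
    path = Path(path)
    report = GlobiReport()
    raw = path.read_bytes()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        report.results.append(RuleResult("utf8", False, ((0, str(exc)),)))
        return report
    report.results.append(RuleResult("utf8", True))

    cr_failures = tuple(
        (lineno, "raw carriage return")
        for lineno, line in enumerate(text.split("\n"), start=1)
        if "\r" in line
    )
    report.results.append(RuleResult("no_carriage_return", not cr_failures, cr_failures))

    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines = lines[:-1]
    if not lines:
        report.results.append(RuleResult("header", False, ((1, "empty file"),)))
        return report

    header = lines[0].split("\t")
    if header == list(GLOBI_COLUMNS):
        report.results.append(RuleResult("header", True))
    else:
        report.results.append(
            RuleResult(
                "header",
                False,
                ((1, f"expected {list(GLOBI_COLUMNS)}, got {header}"),),
            )
        )

    n_fields = len(header)
    count_failures = []
    required_failures = []
    req_idx = {
        col: header.index(col) for col in REQUIRED_NONEMPTY if col in header
    }
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != n_fields:
            count_failures.append(
                (lineno, f"expected {n_fields} fields, got {len(cells)}")
            )
            continue
        for col, idx in req_idx.items():
            if not cells[idx].strip():
                required_failures.append((lineno, f"empty {col}"))
    report.results.append(
        RuleResult("field_count", not count_failures, tuple(count_failures))
    )
    report.results.append(
        RuleResult("required_nonempty", not required_failures, tuple(required_failures))
    )
    return report
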