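# Methods

This note documents the data model, the vocabularies, the file formats,
the query semantics and the synthetic-data generator, together with the
design choices made where the design was genuinely open.

## Record model and validation

A record is a typed, evidenced claim: *subject* relation *object*. Both
roles carry a taxon concept (name, optional rank and external identifier,
and an optional per-record classification path from root to the taxon).
The classification path is stored **per record side**, not in one global
taxonomy, because interaction sources routinely follow different
classifications of the same group (bird and mammal hosts of parasitic
lice are the canonical example); reconciling them is name-resolution
work that is out of scope here.

Validation is *collecting*, not failing: constructors accept anything,
and `validate_record` returns one `Violation` (field, value, rule) per
broken invariant so a curator sees every problem at once. The enforced
invariants are:

* non-empty taxon names; a non-empty classification path must end in the
  taxon name;
* establishment status, interaction status and importance must resolve in
  their closed vocabularies, except for the `unknown` sentinel (statuses
  only). The sentinel exists because the vocabularies are closed lists
  with no null entry, and real records enter the system before curation;
* importance is single-valued or absent — multi-valued importance is
  rejected;
* evidence kind is one of `reference`, `specimen`, `observation`, with a
  non-empty citation;
* a locality needs a name or a complete coordinate pair; latitude in
  [−90, 90], longitude in [−180, 180], decimal degrees, WGS84 assumed
  (no datum field — source data carries none);
* UUIDs are syntactically valid and unique within a dataset.

`organism_part` is deliberately unvalidated verbatim text: sources
predate any shared anatomy vocabulary, and different communities will
eventually want different ones (Uberon for vertebrates, insect-specific
ontologies elsewhere). A pluggable part vocabulary can be layered on
later without changing stored data.

New records get random version-4 UUIDs; importers never reassign an
incoming UUID, since the identifier is the provenance anchor that lets
aggregators route corrections back to the source dataset. The synthetic
generator instead uses name-based (version-5) UUIDs so fixtures are
byte-reproducible.

`reversed_view` materialises the opposite reading of a record (roles
swapped, interaction type replaced by its inverse) without persisting
it; it is an involution, and storage direction is therefore a recorder's
choice — queries compensate (below).

## Vocabularies

Three flat status vocabularies ship with the package as TSV data files:
organism establishment status (aligned to Darwin Core
`establishmentMeans`: Native, Naturalised, Introduced, Invasive,
Captivity, Managed), the wild/captive status of the recorded interaction
(four values covering wild observations and captive rearing from wild or
captive stock), and the importance of the interaction to humans (six
economic/medical/veterinary values). They are reproduced exactly as
curated, including one entry whose description is empty and one whose
uncertainty note sits where the source put it; the loader treats the
files as ground truth rather than guessing intent. Label matching is
case-insensitive on input and canonical (table-cased) on output.

Interaction types form a forest of terms, each with a label, an IRI, an
inverse label/IRI and an optional single parent. The packaged `ro-core`
vocabulary is a hand-curated selection of Relations Ontology terms
(eats/eaten by, the parasite-of family with ecto-/endo- children,
predation, pollination, hosting, and the symmetric "interacts with").
IRIs are opaque strings to the code: their correctness is a
data-curation concern, not a code invariant, and a site can load its own
TSV instead. The single-parent constraint (a forest, not a DAG) matches
the taxonomy-style editing model the vocabulary is meant to support;
multi-parent terms are rejected.

Invariants verified on load and after every mutation: unique labels
(case-insensitive) and IRIs, symmetric inverse pairing, resolvable
parents, no parent cycles. Two deliberate softenings:

* nothing *requires* a child's inverse to be a child of the parent's
  inverse — the relationship between hierarchy and inverses is
  under-specified in practice, so a mismatch is surfaced by `lint()` as
  a warning, not an error (the packaged vocabulary lints clean);
* `add_term` auto-creates the partner term when a new term's inverse
  label resolves to nothing (label/IRI taken from the inverse fields,
  parent mirrored onto the parent's inverse). Without this, the
  every-inverse-resolves invariant would make it impossible to grow the
  vocabulary by new inverse pairs one term at a time.

`descendants(label)` is the reflexive-transitive closure down the
forest; the tests check it against an independent fixpoint traversal of
the raw parent list on hundreds of random forests.

## Tabular exchange

Import is driven by a `ColumnMapping` from record field paths
(`subject.taxon.name`, `locality.latitude`, ...) to source columns, plus
per-field constants, so legacy tables are ingested without reshaping.
The mapping config format is one `field.path = column` per line, with
`!value` marking a constant. Strict mode aborts on the first bad row
with its row number; lenient mode skips bad rows and tallies violations
by field in an `ImportReport`.

Export writes a canonical 20-column file deterministically: fixed column
order, canonical vocabulary casing, UTF-8, LF endings, stable record
order. Delimiter follows the extension (`.csv` comma, everything else
tab). CSV preserves embedded newlines via quoting; TSV cannot, so tabs
and newlines inside values are flattened to spaces with a logged
warning. Compound columns are `|`-joined classification paths and
`;`-joined `kind:citation[:identifier]` evidence items, with literal
separators backslash-escaped (`\|`, `\;`, `\:`, `\\`). Backslash
escaping was chosen over separator doubling because doubling is
ambiguous when an escaped separator abuts a real one (`["a","|b"]` and
`["a|","b"]` would collide) — the property tests found exactly this.

The round-trip contract — write → read → write is byte-identical, with
UUIDs and order preserved — is what makes the canonical file usable as a
storage format for the CLI.

## GloBI exchange file

`export_globi` writes the tab-separated harvest file: one header row,
one row per record in dataset order, absent values as empty fields,
byte-deterministic. The 16-column schema
(`sourceOccurrenceId`, `sourceTaxonName`, `sourceBodyPartName`,
`sourceEstablishmentMeans`, `interactionTypeName`, `interactionTypeId`,
target mirrors, `interactionRecordType`, `importance`, `localityName`,
`decimalLatitude`, `decimalLongitude`, `referenceCitation`,
`evidenceKind`) is **this package's contract**, chosen to carry every
modelled field under GloBI-style column names so a downstream template
mapping is a rename-only step; it is not a reconstruction of any
historical feed's exact headers. The file stays one-row-per-interaction
(matching the one-URL-per-interaction model): only the first
reference-kind evidence is exported as the citation, and the full
evidence mix is summarised as a comma-joined kind list. The `unknown`
sentinel exports as an empty field. `check_globi_file` verifies the
contract (UTF-8, exact header, constant field count, no stray carriage
returns, non-empty taxa and interaction type per row) and reports
per-rule findings with line numbers instead of raising.

## Query semantics

Criteria combine by conjunction only — the semantics of a faceted search
page, not a boolean query language. A record matches if its forward
reading satisfies all present criteria, or (with `match_inverse` on) if
its reversed view does, role-specific criteria then applying to the
reversed roles. Type criteria expand to descendant terms when
`expand_hierarchy` is on. Both flags default on, because hierarchy and
inverse IRIs are stored precisely to enable direction- and
granularity-insensitive retrieval. Taxon matching is exact string
equality against the role's name or any classification-path element; no
fuzzy or synonym matching. Facet counts are computed over the filtered
set; zero-count values are omitted, `unknown` counts as its own value,
and records lacking an optional field (importance) fall into no bucket,
so counts sum to the result size only for always-present fields.

The central correctness argument is dual-route: the test suite evaluates
random criteria over seeded datasets with both `filter_records` and an
independent naive per-record evaluator (its own traversal and inverse
resolution) and requires identical results.

## Synthetic data

The generator emulates the two archetypes the model was shaped around:

* **herbivory** — phasmid/lepidopteran herbivores on host plants, typed
  "eats", with a `cluster_fraction` (default 0.15) of records drawn as
  an introduced stick insect on introduced plants — the curatorial trap
  the establishment-status machinery exists to separate out;
* **parasitism** — lice on bird/mammal hosts, typed "ectoparasite of",
  with organism parts from {wings, head and neck, rump};
* **mixed** — an even blend (default).

Defaults: 100 records; establishment statuses drawn per side from
{Native 0.55, Introduced 0.20, Naturalised 0.10, Invasive 0.05, Managed
0.05, Captivity 0.05} — a majority-native mix with a substantial
introduced minority, so exclusion queries have non-trivial answers;
captive interaction status with probability 0.2 (captive rearing is
common in the source material but not dominant); organism part with
probability 0.3; importance with probability 0.15; locality with
probability 0.6, a quarter of those name-only. Every record gets at
least one evidence item (reference-weighted), matching the
documented-in-a-reference origin of such datasets.

The generator also returns a `GeneratorTally` of exact per-value counts
and the list of records in which neither side is Introduced; these are
the independent expectations the facet and exclusion-query tests compare
against.

What the fixtures do **not** emulate: misspelled or synonymous taxon
names, conflicting classifications of the same taxon, sparse or
contradictory coordinates, free-text noise in parts and citations, and
skewed real-world degree distributions (a few hosts carrying most
records). Tests passing on fixtures therefore demonstrate the
correctness of the machinery (validation, round trips, retrieval
semantics), not robustness to dirty real data — importing a real legacy
table will exercise the lenient import path far harder.

## Numerical and procedural choices

* Problem sizes in the test suite and acceptance script (datasets of
  1,000 records for query oracles, 100 × 25-record fixtures for round
  trips, 200 random forests up to 1,000 terms, 1,000 mutations) are
  chosen to exercise the properties at a scale where bookkeeping errors
  surface, while keeping a full run in seconds.
* Coordinates round-trip through Python's shortest-repr float
  formatting, so serialisation is lossless.
* Record equality is plain dataclass field equality; the involution and
  round-trip properties rely on canonicalising vocabulary labels at
  record creation and import.
* Locality substring matching is case-insensitive; taxon matching is
  case-sensitive exact (taxon names are proper names; status labels are
  vocabulary entries with known casing).
* Ties/degenerate inputs: an empty dataset exports a header-only file;
  an empty criteria object matches everything; `descendants` of a leaf
  is the leaf itself.

## Known limitations

* No name reconciliation, synonym handling or fuzzy matching.
* Single-parent term hierarchies only; no OWL reasoning and no
  abiotic-interaction terms.
* No event dates on records, and no per-field licensing (a dataset-level
  metadata block carries provenance and licence).
* The exchange-file schema is self-defined (documented above); wire
  compatibility with any specific historical harvest feed is not
  claimed.
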