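# ecointeractions

A library and command-line toolkit for curating **species-interaction
records**: structured statements that one organism stands in a typed
ecological relation to another — a caterpillar *eats* a host plant, a louse
is an *ectoparasite of* a bird — together with the evidence for the claim,
the locality, and curatorial status values drawn from controlled
vocabularies. It is aimed at the kind of desk-scale datasets biodiversity
researchers accumulate (host-plant catalogues, parasite/host checklists)
and at making those datasets harvestable by aggregators such as
[Global Biotic Interactions (GloBI)](https://www.globalbioticinteractions.org/).

## The data model

Each `InteractionRecord` holds:

* **subject** and **object** roles — a taxon (with an optional per-record
  classification path, since different sources follow different
  classifications), an *establishment status* aligned to Darwin Core
  `establishmentMeans` (Native, Naturalised, Introduced, Invasive,
  Captivity, Managed), and a verbatim free-text *organism part* ("wings",
  "head and neck", "flowers");
* an **interaction type** from a hierarchical vocabulary of Relations
  Ontology style terms, each carrying its IRI and its inverse ("eaten by"
  is the inverse of "eats"; "ectoparasite of" is a child of "parasite
  of");
* a **wild/captive status** of the recorded interaction and an optional
  **importance** value (economic, medical, veterinary);
* **evidence** (references, specimens, observations), an optional
  **locality** (name and/or WGS84 coordinates), and a persistent **UUID**
  that survives aggregation so corrections can flow back to the source.

Two retrieval features exploit the vocabulary structure, both on by
default: hierarchy expansion (a "parasite of" query also returns records
typed "ectoparasite of") and inverse matching (a record stored as louse →
host is found by the host → louse query, with role criteria evaluated
against the reversed view).

## Worked example

Generate a small seeded synthetic dataset of herbivory records, then ask
the motivating curatorial question — *which of these feeding records
involve only organisms that are not introduced?*

```
$ ecointeractions fixture --seed 42 --n 5 --archetype herbivory --out demo.tsv
$ ecointeractions query --dataset demo.tsv --facet subject_status
Captivity	1
Introduced	3
Naturalised	1
$ ecointeractions query --dataset demo.tsv --type eats \
    --exclude-subject-status Introduced --exclude-object-status Introduced
d0d7191a-4df8-573d-912c-581424769b8a	Medauroidea extradentata	eats	Rosa sp.
81692985-0006-596b-bcd4-04da20925a7d	Medauroidea extradentata	eats	Pinus ponderosa
```

The facet output lists each establishment status of the herbivore side
with its record count (3 of the 5 subjects are Introduced — among them the
*Carausius morosus*-style cluster of an introduced stick insect feeding on
introduced plants). The exclusion query drops every record in which either
side is Introduced, leaving the two records shown (one UUID, subject,
interaction type and object per line).

Export for harvest and self-check the exchange contract:

```
$ ecointeractions export-globi --dataset demo.tsv --out interactions.txt
$ ecointeractions check-globi --in interactions.txt
utf8: pass
no_carriage_return: pass
header: pass
field_count: pass
required_nonempty: pass
```

The same operations are available as library functions
(`generate_fixture`, `filter_records`, `facet_counts`, `export_globi`,
`read_dataset`/`write_dataset`, ...); see the docstrings and
`docs/methods.md` for the file formats and the semantics of each step.

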