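import random

import pytest
from hypothesis import given, strategies as st

from ecointeractions import (
    ColumnMapping,
    Dataset,
    EvidenceSource,
    FixtureSpec,
    generate_fixture,
    read_dataset,
    write_dataset,
)
from ecointeractions.errors import MappingError, TabularImportError
from ecointeractions.tabular_io import (
    CANONICAL_COLUMNS,
    parse_classification,
    parse_evidence,
    serialize_classification,
    serialize_evidence,
)


LOUSE_TSV = "\n".join([
    "parasite\thost\trelation\trecid",
    "Columbicola columbae\tColumba livia\tectoparasite of\t11111111-1111-4111-8111-111111111111",
    "Trichodectes canis\tCanis lupus\tectoparasite of\t22222222-2222-4222-8222-222222222222",
    "Pediculus schaeffi\tPan troglodytes\tparasite of\t33333333-3333-4333-8333-333333333333",
]) + "\n"

LOUSE_MAPPING = ColumnMapping(
    assignments={
        "subject.taxon.name": "parasite",
        "object.taxon.name": "host",
        "interaction_type": "relation",
        "uuid": "recid",
    },
)


class TestColumnMapping:
    def test_required_paths_must_be_covered(self):
        with pytest.raises(MappingError, match="interaction_type"):
            ColumnMapping(assignments={
                "subject.taxon.name": "a", "object.taxon.name": "b",
            })

    def test_constant_can_cover_a_required_path(self):
        ColumnMapping(
            assignments={"subject.taxon.name": "a", "object.taxon.name": "b"},
            constants={"interaction_type": "eats"},
        )

    def test_assigned_and_constant_conflict(self):
        with pytest.raises(MappingError, match="both assigned and constant"):
            ColumnMapping(
                assignments={
                    "subject.taxon.name": "a", "object.taxon.name": "b",
                    "interaction_type": "c",
                },
                constants={"interaction_type": "eats"},
            )

    def test_unknown_field_path(self):
        with pytest.raises(MappingError, match="unknown field path"):
            ColumnMapping(assignments={"subject.wingspan": "w"})

    def test_from_file_parses_columns_and_constants(self, tmp_path):
        config = tmp_path / "mapping.conf"
        config.write_text(
            "# louse table\n"
            "subject.taxon.name = parasite\n"
            "object.taxon.name = host\n"
            "interaction_type = !ectoparasite of\n"
        )
        mapping = ColumnMapping.from_file(config)
        assert mapping.assignments["subject.taxon.name"] == "parasite"
        assert mapping.constants["interaction_type"] == "ectoparasite of"


class TestRead:
    def test_clean_file_strict(self, tmp_path):
        path = tmp_path / "lice.tsv"
        path.write_text(LOUSE_TSV)
        dataset, report = read_dataset(path, LOUSE_MAPPING, strict=True)
        assert len(dataset) == 3
        assert report.rows_read == 3
        assert report.rows_skipped == 0
        # incoming UUIDs preserved verbatim, file order kept
        assert [r.uuid[:1] for r in dataset] == ["1", "2", "3"]
        assert dataset.records[0].subject.taxon.name == "Columbicola columbae"

    def test_misspelled_type_lenient_skips_and_reports(self, tmp_path):
        path = tmp_path / "lice.tsv"
        path.write_text(LOUSE_TSV.replace("parasite of\t3", "parasiteof\t3"))
        dataset, report = read_dataset(path, LOUSE_MAPPING, strict=False)
        assert len(dataset) == 2
        assert report.rows_skipped == 1
        assert report.violations_by_field["interaction_type"] == 1

    def test_misspelled_type_strict_aborts_with_row_number(self, tmp_path):
        path = tmp_path / "lice.tsv"
        path.write_text(LOUSE_TSV.replace("parasite of\t3", "parasiteof\t3"))
        with pytest.raises(TabularImportError, match="row 4"):
            read_dataset(path, LOUSE_MAPPING, strict=True)

    def test_duplicate_uuid_strict_and_lenient(self, tmp_path):
        path = tmp_path / "lice.tsv"
        path.write_text(LOUSE_TSV.replace("33333333-3333-4333-8333-333333333333",
                                          "11111111-1111-4111-8111-111111111111"))
        with pytest.raises(TabularImportError, match="duplicate uuid"):
            read_dataset(path, LOUSE_MAPPING, strict=True)
        dataset, report = read_dataset(path, LOUSE_MAPPING, strict=False)
        assert len(dataset) == 2
        assert report.violations_by_field["uuid"] == 1

    def test_rows_without_uuid_get_fresh_valid_uuids(self, tmp_path):
        mapping = ColumnMapping(assignments={
            "subject.taxon.name": "parasite",
            "object.taxon.name": "host",
            "interaction_type": "relation",
        })
        path = tmp_path / "lice.tsv"
        path.write_text(LOUSE_TSV)
        dataset, _ = read_dataset(path, mapping, strict=True)
        assert len({r.uuid for r in dataset}) == 3

    def test_missing_mapped_column_fails_before_reading_rows(self, tmp_path):
        path = tmp_path / "lice.tsv"
        path.write_text(LOUSE_TSV.replace("parasite\t", "bug\t"))
        with pytest.raises(MappingError, match="parasite"):
            read_dataset(path, LOUSE_MAPPING, strict=True)

    def test_constants_apply_to_every_row(self, tmp_path):
        mapping = ColumnMapping(
            assignments={
                "subject.taxon.name": "parasite",
                "object.taxon.name": "host",
                "uuid": "recid",
            },
            constants={
                "interaction_type": "ectoparasite of",
                "subject.establishment_status": "native",
            },
        )
        path = tmp_path / "lice.tsv"
        path.write_text(LOUSE_TSV)
        dataset, _ = read_dataset(path, mapping, strict=True)
        assert all(r.interaction_type == "ectoparasite of" for r in dataset)
        assert all(r.subject.establishment_status == "Native" for r in dataset)

    def test_created_records_equal_independently_valid_rows(self, tmp_path, vocabs):
        """Lenient import count agrees with a direct row-by-row validity check."""
        dataset, _ = generate_fixture(FixtureSpec(seed=21, n_records=500), vocabs)
        path = tmp_path / "fixture.tsv"
        write_dataset(dataset, path)

        # corrupt a deterministic sample of rows in-place
        rng = random.Random(99)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        bad_rows = rng.sample(range(1, len(lines)), 40)
        for i in bad_rows:
            cells = lines[i].split("\t")
            column, junk = rng.choice([
                ("interaction_type", "chews"),
                ("subject_establishment_status", "Alien"),
                ("interaction_status", "in a lab"),
                ("importance", "Cosmic"),
                ("decimal_latitude", "north-ish"),
            ])
            cells[header.index(column)] = junk
            lines[i] = "\t".join(cells)
        path.write_text("\n".join(lines) + "\n")

        # independent oracle: validate raw cells directly against the tables
        org = {l.lower() for l in vocabs.organism_status.labels} | {"unknown", ""}
        ist = {l.lower() for l in vocabs.interaction_status.labels} | {"unknown", ""}
        imp = {l.lower() for l in vocabs.importance.labels} | {""}
        types = {t.label.lower() for t in vocabs.interaction_types.terms}

        def row_valid(cells):
            get = lambda col: cells[header.index(col)]
            try:
                float(get("decimal_latitude") or "0")
                float(get("decimal_longitude") or "0")
            except ValueError:
                return False
            return (
                get("interaction_type").lower() in types
                and get("subject_establishment_status").lower() in org
                and get("object_establishment_status").lower() in org
                and get("interaction_status").lower() in ist
                and get("importance").lower() in imp
            )

        expected = sum(row_valid(line.split("\t")) for line in lines[1:])
        reread, report = read_dataset(path, strict=False)
        assert len(reread) == expected == 500 - len(bad_rows)
        assert report.rows_skipped == len(bad_rows)


class TestWriteRoundTrip:
    def test_empty_dataset_writes_header_only(self, tmp_path, vocabs):
        path = write_dataset(Dataset(vocabularies=vocabs), tmp_path / "empty.tsv")
        lines = path.read_text().splitlines()
        assert lines == ["\t".join(col for _, col in CANONICAL_COLUMNS)]

    @pytest.mark.parametrize("ext", ["tsv", "csv"])
    def test_write_read_write_is_byte_identical(self, tmp_path, vocabs, ext):
        dataset, _ = generate_fixture(FixtureSpec(seed=3, n_records=120), vocabs)
        first = write_dataset(dataset, tmp_path / f"a.{ext}")
        reread, report = read_dataset(first, strict=True)
        assert report.rows_skipped == 0
        second = write_dataset(reread, tmp_path / f"b.{ext}")
        assert first.read_bytes() == second.read_bytes()
        assert [r.uuid for r in reread] == [r.uuid for r in dataset]

    def test_round_trip_preserves_every_field(self, tmp_path, vocabs):
        dataset, _ = generate_fixture(FixtureSpec(seed=4, n_records=200), vocabs)
        path = write_dataset(dataset, tmp_path / "d.tsv")
        reread, _ = read_dataset(path, strict=True)
        assert reread.records == dataset.records

    def test_csv_preserves_embedded_newlines_and_delimiters(self, tmp_path, vocabs):
        dataset = Dataset(vocabularies=vocabs)
        from ecointeractions import Locality, OrganismRole, TaxonConcept

        dataset.create_record(
            OrganismRole(taxon=TaxonConcept(name="Columbicola columbae"),
                         organism_part="head and neck,\nor rump"),
            OrganismRole(taxon=TaxonConcept(
                name="Columba livia",
                classification_path=("Animalia", "odd|pipe", "Columba livia"),
            )),
            "ectoparasite of",
            evidence=[EvidenceSource(kind="reference",
                                     citation="Clay: louse; fauna, 1951")],
            locality=Locality(name="London, UK"),
        )
        path = write_dataset(dataset, tmp_path / "d.csv")
        reread, _ = read_dataset(path, strict=True)
        assert reread.records == dataset.records


classification_texts = st.lists(
    st.text(
        alphabet=st.characters(blacklist_characters="\t\n\r", blacklist_categories=("Cs",)),
        min_size=1, max_size=12,
    ),
    min_size=1, max_size=5,
)


class TestEscaping:
    @given(classification_texts)
    def test_classification_path_escaping_round_trips(self, path):
        assert parse_classification(serialize_classification(tuple(path))) == tuple(path)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["reference", "specimen", "observation"]),
                st.text(
                    alphabet=st.characters(
                        blacklist_characters="\t\n\r", blacklist_categories=("Cs",)
                    ),
                    min_size=1, max_size=20,
                ),
                st.one_of(st.none(), st.text(
                    alphabet=st.characters(
                        blacklist_characters="\t\n\r", blacklist_categories=("Cs",)
                    ),
                    max_size=10,
                )),
            ),
            min_size=1, max_size=4,
        )
    )
    def test_evidence_escaping_round_trips(self, items):
        evidence = tuple(
            EvidenceSource(kind=k, citation=c, identifier=i) for k, c, i in items
        )
        assert parse_evidence(serialize_evidence(evidence)) == evidence
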