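import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpdselect import (
    MatchStatus,
    ProjectRecord,
    ProjectStatus,
    TaxonomyEntry,
    candidate_filter,
    match_record,
    normalize_strain_name,
    strains_equal,
)
from rpdselect.errors import TableFormatError
from rpdselect.matching import (
    MatchResult,
    extract_species_names,
    read_registry_tsv,
    read_taxonomy_tsv,
    strain_keys,
    write_matches_tsv,
)

TAXONOMY = [
    TaxonomyEntry(
        accepted_species="Ktedonobacter racemifer",
        type_strain_deposits=frozenset({"SOSP1-21", "DSM 44963"}),
    ),
    TaxonomyEntry(
        accepted_species="Gemmata obscuriglobus",
        synonyms=frozenset({"Gemmata obscuriglobus", "Gemmata antiqua"}),
        type_strain_deposits=frozenset({"ATCC 49354", "DSM 5831"}),
    ),
]


class TestNormalization:
    def test_trailing_type_marker_ignored(self):
        assert strains_equal("DSM 44963T", "DSM 44963")
        assert normalize_strain_name("DSM 44963T") == normalize_strain_name("DSM 44963")

    def test_underscore_is_a_retained_character(self):
        # hyphens vanish, underscores stay: these are distinct names
        assert not strains_equal("sosp1-21", "SOSP1_21")

    def test_case_and_separators_ignored(self):
        assert strains_equal("ATCC  33277 T", "atcc33277")

    def test_empty_after_stripping_rejected(self):
        with pytest.raises(ValueError):
            normalize_strain_name("--- ---")

    def test_idempotent_on_collection_style_names(self):
        for name in ("DSM 44963T", "ATCC 33277", "SOSP1-21", "CIP 107 T", "NBRC 12345"):
            canon = normalize_strain_name(name)
            assert normalize_strain_name(canon) == canon

    @given(
        st.text(alphabet="abcdefgh", min_size=1, max_size=6),
        st.integers(min_value=0, max_value=99999),
    )
    @settings(max_examples=100, deadline=None)
    def test_rule_preserving_edits_never_split_a_class(self, prefix, number):
        base = f"{prefix.upper()} {number}"
        variants = [
            base.lower(),
            base.replace(" ", ""),
            base.replace(" ", "-"),
            base + "T",
            base + " T",
            f" {base} ",
            base.swapcase(),
        ]
        for v in variants:
            assert strains_equal(base, v), (base, v)

    @given(
        st.text(alphabet="abcdefgh", min_size=1, max_size=6),
        st.integers(min_value=0, max_value=9999),
        st.integers(min_value=0, max_value=9),
    )
    @settings(max_examples=100, deadline=None)
    def test_inserting_a_digit_always_changes_the_class(self, prefix, number, extra):
        base = f"{prefix} {number}"
        assert not strains_equal(base, f"{base}{extra}x")
        assert not strains_equal(base, f"{prefix} {number}{extra}0")

    def test_equivalence_is_symmetric(self):
        pairs = [("DSM 1T", "dsm1"), ("A-B-1", "ab1"), ("x 9 T", "X9")]
        for a, b in pairs:
            assert strains_equal(a, b) == strains_equal(b, a)

    def test_keys_contain_both_forms(self):
        assert strain_keys("DSM 1T") == frozenset({"dsm1t", "dsm1"})


class TestSpeciesExtraction:
    def test_binomial_prefix_extracted_from_organism_name(self):
        record = ProjectRecord(
            record_id="r1", organism_name="Ktedonobacter racemifer SOSP1-21"
        )
        assert "Ktedonobacter racemifer" in extract_species_names(record)

    def test_full_field_value_is_a_candidate(self):
        record = ProjectRecord(record_id="r1", species_field="Gemmata antiqua")
        assert "Gemmata antiqua" in extract_species_names(record)


class TestMatchRecord:
    def test_found_complete_via_relaxed_strain_match(self):
        record = ProjectRecord(
            record_id="r1",
            organism_name="Ktedonobacter racemifer",
            strain_field="SOSP1-21T",
            project_status=ProjectStatus.COMPLETE,
        )
        result = match_record(record, TAXONOMY)
        assert result.status is MatchStatus.FOUND_COMPLETE
        assert result.matched_species == "Ktedonobacter racemifer"
        assert result.matched_deposit == "SOSP1-21"

    def test_found_incomplete_for_incomplete_project(self):
        record = ProjectRecord(
            record_id="r1",
            organism_name="Ktedonobacter racemifer",
            strain_field="DSM44963",
            project_status=ProjectStatus.INCOMPLETE,
        )
        assert match_record(record, TAXONOMY).status is MatchStatus.FOUND_INCOMPLETE

    def test_species_not_found(self):
        record = ProjectRecord(record_id="r1", organism_name="Unknownus examplei XYZ")
        result = match_record(record, TAXONOMY)
        assert result.status is MatchStatus.SPECIES_NOT_FOUND
        assert result.matched_species is None
        assert result.matched_deposit is None

    def test_strains_not_found(self):
        record = ProjectRecord(
            record_id="r1",
            organism_name="Ktedonobacter racemifer",
            strain_field="XYZ-999",
        )
        result = match_record(record, TAXONOMY)
        assert result.status is MatchStatus.STRAINS_NOT_FOUND
        assert result.matched_species == "Ktedonobacter racemifer"
        assert result.matched_deposit is None

    def test_synonym_resolves_to_accepted_species(self):
        record = ProjectRecord(
            record_id="r1",
            species_field="Gemmata antiqua",
            strain_field="dsm 5831 T",
            project_status=ProjectStatus.COMPLETE,
        )
        result = match_record(record, TAXONOMY)
        assert result.status is MatchStatus.FOUND_COMPLETE
        assert result.matched_species == "Gemmata obscuriglobus"

    def test_strain_embedded_in_organism_name(self):
        record = ProjectRecord(
            record_id="r1",
            organism_name="Ktedonobacter racemifer SOSP1-21",
            project_status=ProjectStatus.COMPLETE,
        )
        assert match_record(record, TAXONOMY).status is MatchStatus.FOUND_COMPLETE

    def test_every_record_gets_exactly_one_status(self):
        records = [
            ProjectRecord(record_id=f"r{i}", organism_name=name)
            for i, name in enumerate(
                ["Ktedonobacter racemifer", "Nobody knowsi", "Gemmata obscuriglobus X1"]
            )
        ]
        statuses = [match_record(r, TAXONOMY).status for r in records]
        assert all(isinstance(s, MatchStatus) for s in statuses)

    def test_empty_taxonomy_rejected(self):
        with pytest.raises(ValueError):
            match_record(ProjectRecord(record_id="r", organism_name="X y"), [])


class TestCandidateFilter:
    def test_candidates_are_unfound_records(self):
        results = [
            MatchResult("a", MatchStatus.FOUND_COMPLETE),
            MatchResult("b", MatchStatus.STRAINS_NOT_FOUND, "S"),
            MatchResult("c", MatchStatus.SPECIES_NOT_FOUND),
        ]
        assert candidate_filter(results) == {"b", "c"}

    def test_all_found_and_empty(self):
        assert candidate_filter([MatchResult("a", MatchStatus.FOUND_COMPLETE)]) == set()
        assert candidate_filter([]) == set()


class TestTsvIO:
    def test_registry_roundtrip(self, tmp_path):
        path = tmp_path / "registry.tsv"
        path.write_text(
            "record_id\torganism_name\tspecies\tncbi_project_name\tstrain\t"
            "culture_collection\tstatus\n"
            "r1\tKtedonobacter racemifer SOSP1-21\t\t\tSOSP1-21T\tDSM 44963\tcomplete\n"
        )
        records = read_registry_tsv(path)
        assert records[0].record_id == "r1"
        assert records[0].project_status is ProjectStatus.COMPLETE

    def test_registry_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "registry.tsv"
        path.write_text("record_id\torganism_name\n" "r1\tX y\n")
        with pytest.raises(TableFormatError, match="species"):
            read_registry_tsv(path)

    def test_taxonomy_read_and_match_output(self, tmp_path):
        tax_path = tmp_path / "taxonomy.tsv"
        tax_path.write_text(
            "accepted_species\tsynonyms\ttype_strain_deposits\n"
            "Ktedonobacter racemifer\t\tSOSP1-21;DSM 44963\n"
        )
        entries = read_taxonomy_tsv(tax_path)
        assert entries[0].accepted_species in entries[0].synonyms
        out = tmp_path / "matches.tsv"
        write_matches_tsv(
            [MatchResult("r1", MatchStatus.FOUND_COMPLETE, "K r", "SOSP1-21")], out
        )
        assert "found_complete" in out.read_text()
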