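"""Harmonization engine: cell cleaning, ids, composites, full runs."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metaharm.config import AttributeSpec, HarmonizationConfig
from metaharm.curation import CurationMap, CurationMapEntry
from metaharm.engine import (
    SchemaError,
    binary_to_descriptive,
    build_composite,
    consolidate_most_specific,
    harmonize_table,
    make_curation_id,
    normalize_missing,
    parse_composite,
    parse_curation_id,
    split_numeric_unit,
)
from metaharm.issues import IssueKind
from metaharm.util import is_na

NA_TOKENS = ["", "na", "n/a", "null", "missing", "-", "999"]


class TestNormalizeMissing:
    @pytest.mark.parametrize(
        "cell,expected",
        [
            ("999", None),
            ("", None),
            ("  ", None),
            ("NULL", None),
            ("Missing", None),
            ("-", None),
            ("99", "99"),
            ("Unknown", "Unknown"),  # legal category, not an NA token
            ("apple", "apple"),
        ],
    )
    def test_token_set(self, cell, expected):
        assert normalize_missing(cell, NA_TOKENS) == expected


class TestBinaryToDescriptive:
    def test_yes_no_labels(self):
        col, issues = binary_to_descriptive(
            ["yes", "no", None],
            ["yes"],
            ["no"],
            "Antibiotics Therapy",
            "No Antibiotics Therapy",
        )
        assert col == ["Antibiotics Therapy", "No Antibiotics Therapy", None]
        assert issues == []

    def test_zero_one_coded_column(self):
        col, issues = binary_to_descriptive(
            ["1", "0", "1", "0", "0", "1"], ["1"], ["0"], "Present", "Absent"
        )
        assert col == ["Present", "Absent", "Present", "Absent", "Absent", "Present"]
        assert issues == []

    def test_non_interpretable_token_logged(self):
        col, issues = binary_to_descriptive(["maybe"], ["yes"], ["no"], "P", "A")
        assert col == [None]
        assert len(issues) == 1 and issues[0].kind == IssueKind.NON_INTERPRETABLE


class TestSplitNumericUnit:
    @pytest.mark.parametrize(
        "cell,default,expected",
        [
            ("34 years", "years", (34.0, "years")),
            ("6.5", "months", (6.5, "months")),
            ("unknown", "years", (None, None)),
            ("12 mg/L", "", (12.0, "mg/L")),
            (None, "years", (None, None)),
        ],
    )
    def test_parse(self, cell, default, expected):
        assert split_numeric_unit(cell, default) == expected


class TestConsolidateMostSpecific:
    def test_child_beats_subsuming_parent(self, graph):
        # Metastatic Neoplasm is_a Neoplasm in the toy ontology
        winner, issues = consolidate_most_specific(
            ["TOY:0000101", "TOY:0000103"], graph
        )
        assert winner == "TOY:0000103"
        assert issues == []

    def test_single_token_returns_itself(self, graph):
        winner, _ = consolidate_most_specific(["TOY:0000101"], graph)
        assert winner == "TOY:0000101"

    def test_equal_depth_siblings_tie_lexicographic(self, graph):
        winner, issues = consolidate_most_specific(
            ["TOY:0000103", "TOY:0000102"], graph
        )
        assert winner == "TOY:0000102"
        assert [i.kind for i in issues] == [IssueKind.TIE]

    def test_unresolvable_token_passes_through_with_issue(self, graph):
        winner, issues = consolidate_most_specific(["NOPE:1"], graph)
        assert winner == "NOPE:1"
        assert [i.kind for i in issues] == [IssueKind.NON_INTERPRETABLE]


class TestCurationId:
    def test_three_part_id(self):
        assert (
            make_curation_id("luad_msk_npjpo_2021", "P01", "S01")
            == "luad_msk_npjpo_2021:P01:S01"
        )

    def test_participant_level_id(self):
        assert make_curation_id("studyA", "p1", None) == "studyA:p1"

    def test_empty_components_rejected(self):
        with pytest.raises(ValueError):
            make_curation_id("", "p1")
        with pytest.raises(ValueError):
            make_curation_id("s", "")

    @settings(max_examples=200, derandomize=True)
    @given(
        st.text(min_size=1, max_size=10),
        st.text(min_size=1, max_size=10),
        st.one_of(st.none(), st.text(min_size=1, max_size=10)),
    )
    def test_roundtrip_with_separator_escaping(self, study, participant, sample):
        cid = make_curation_id(study, participant, sample)
        assert parse_curation_id(cid) == (study, participant, sample)


class TestComposite:
    def test_serialization_contract(self):
        cell = build_composite(
            {"CRP": "12 mg/L", "IL6": "3 pg/mL"}, ["CRP", "IL6", "TNF"]
        )
        assert cell == "CRP:12 mg/L;IL6:3 pg/mL"

    def test_empty_map_is_na(self):
        assert build_composite({}, ["CRP"]) is None

    def test_unregistered_subfield_rejected(self):
        with pytest.raises(SchemaError):
            build_composite({"XX": "1"}, ["CRP"])

    @settings(max_examples=1000, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(["CRP", "IL6", "TNF", "CA125", "PSA"]),
            st.text(
                alphabet=st.characters(blacklist_characters=";", min_codepoint=32),
                min_size=1,
                max_size=8,
            ),
            max_size=5,
        )
    )
    def test_parse_build_identity(self, parts):
        registry = ["CRP", "IL6", "TNF", "CA125", "PSA"]
        cell = build_composite(parts, registry)
        parsed = parse_composite(cell)
        stripped = {k: v.strip() for k, v in parts.items() if v.strip()}
        assert {k: v for k, v in parsed.items()} == stripped


def _mini_config(**overrides) -> HarmonizationConfig:
    base = dict(
        attributes=[
            AttributeSpec(
                name="color",
                structure="single",
                source_fields=["color_a", "color_b"],
                map="color",
            )
        ],
        maps={"color": "color.tsv"},
    )
    base.update(overrides)
    return HarmonizationConfig(**base)


def _color_map() -> CurationMap:
    return CurationMap(
        "color",
        [
            CurationMapEntry("red", "Red", "CLR:0000001"),
            CurationMapEntry("blu", "Blue", "CLR:0000002"),
        ],
    )


class TestHarmonizeTable:
    def test_zero_rows_keeps_all_columns(self):
        raw = pd.DataFrame(
            columns=["study_name", "participant_id", "sample_id", "color_a", "color_b"]
        )
        res = harmonize_table(raw, _mini_config(), {"color": _color_map()})
        for col in (
            "curation_id",
            "curated_color",
            "curated_color_ontology_term_id",
            "curated_color_source",
            "original_color_value",
            "last_modified",
        ):
            assert col in res.table.data.columns
        assert len(res.table) == 0

    def test_known_cells_and_provenance(self):
        raw = pd.DataFrame(
            {
                "study_name": ["s", "s", "s"],
                "participant_id": ["p1", "p2", "p3"],
                "sample_id": ["a", "b", "c"],
                "color_a": ["red", None, "999"],
                "color_b": [None, "blu", "red"],
            }
        )
        res = harmonize_table(raw, _mini_config(), {"color": _color_map()}, timestamp="T")
        df = res.table.data
        assert list(df["curated_color"]) == ["Red", "Blue", "Red"]
        assert list(df["curated_color_source"]) == ["color_a", "color_b", "color_b"]
        # original value keeps the pre-cleaning content, NA tokens included
        assert df["original_color_value"][2] == "999;red"

    def test_missing_source_column_is_hard_error(self):
        raw = pd.DataFrame(
            {"study_name": ["s"], "participant_id": ["p"], "sample_id": ["x"]}
        )
        with pytest.raises(SchemaError, match="color_a"):
            harmonize_table(raw, _mini_config(), {"color": _color_map()})

    def test_unknown_map_reference_is_hard_error(self):
        raw = pd.DataFrame(
            {
                "study_name": ["s"],
                "participant_id": ["p"],
                "sample_id": ["x"],
                "color_a": ["red"],
                "color_b": [None],
            }
        )
        with pytest.raises(SchemaError, match="map"):
            harmonize_table(raw, _mini_config(), {})

    def test_conflicting_single_sources_log_conflict(self):
        raw = pd.DataFrame(
            {
                "study_name": ["s"],
                "participant_id": ["p"],
                "sample_id": ["x"],
                "color_a": ["red"],
                "color_b": ["blu"],
            }
        )
        res = harmonize_table(raw, _mini_config(), {"color": _color_map()})
        assert res.table.data["curated_color"][0] == "Red"  # leftmost wins
        assert [i.kind for i in res.issues] == [IssueKind.CONFLICT]

    def test_sparse_columns_union_completeness(self):
        """Five <20%-complete subfield columns merge into one composite
        whose completeness equals the union coverage."""
        n = 50
        subs = [f"g{i}" for i in range(5)]
        cols = {s: [None] * n for s in subs}
        covered = set()
        for i, s in enumerate(subs):
            for r in range(i * 9, i * 9 + 9):  # 9/50 = 18% each, disjoint
                cols[s][r] = "x"
                covered.add(r)
        raw = pd.DataFrame(
            {
                "study_name": ["s"] * n,
                "participant_id": [f"p{r}" for r in range(n)],
                "sample_id": ["a"] * n,
                **cols,
            }
        )
        config = HarmonizationConfig(
            attributes=[
                AttributeSpec(name="geno", structure="composite", source_fields=subs)
            ]
        )
        res = harmonize_table(raw, config, {})
        from metaharm.metrics import completeness

        got = completeness(res.table.data["curated_geno"])
        assert got == pytest.approx(len(covered) / n)
        for s in subs:
            single = completeness(raw[s])
            assert single is not None and got >= single

    def test_determinism_given_pinned_timestamp(self):
        raw = pd.DataFrame(
            {
                "study_name": ["s", "s"],
                "participant_id": ["p1", "p2"],
                "sample_id": ["a", "b"],
                "color_a": ["red", "blu"],
                "color_b": [None, None],
            }
        )
        a = harmonize_table(raw, _mini_config(), {"color": _color_map()}, timestamp="T")
        b = harmonize_table(raw, _mini_config(), {"color": _color_map()}, timestamp="T")
        assert a.table.data.equals(b.table.data)


def test_provenance_is_lossless_on_generated_fixture():
    """original_{a}_value plus curated_{a}_source relocate the raw cells."""
    from metaharm.simulate import CorruptionProfile, make_messy_metadata, make_toy_ontology
    from metaharm.util import split_cell

    onto = make_toy_ontology(seed=1)
    bundle = make_messy_metadata(CorruptionProfile(seed=3, n_participants=40), onto)
    res = harmonize_table(bundle.messy, bundle.config, bundle.maps, onto.graph, timestamp="T")
    df = res.table.data
    for spec in bundle.config.attributes:
        orig_col = f"original_{spec.name}_value"
        for i in range(len(df)):
            raw_parts = [
                str(bundle.messy[f].iloc[i])
                for f in spec.source_fields
                if not is_na(bundle.messy[f].iloc[i])
            ]
            expected = ";".join(raw_parts) if raw_parts else None
            got = df[orig_col].iloc[i]
            assert (is_na(got) and expected is None) or got == expected
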