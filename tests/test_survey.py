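"""Ingestion, round-trip, splitting and stratification of survey tables."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kanosight import (
    KanosightError,
    ParseError,
    SchemaError,
    SurveyDataset,
    read_survey,
    read_survey_wide,
    split_groups,
    stratify,
)
from kanosight.survey import wide_to_long


def _write_long(tmp_path, rows, header="respondent_id,attribute_id,functional,dysfunctional,relevance"):
    path = tmp_path / "survey.csv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


class TestReadSurvey:
    def test_reads_canonical_tokens_unchanged(self, tmp_path):
        path = _write_long(tmp_path, [
            "r1,a,expected,dislike,very_important",
            "r2,a,delighted,expected,important",
            "r3,a,neutral,tolerated,neutral",
        ])
        data = read_survey(path)
        assert len(data) == 3
        assert list(data.records["functional"]) == ["expected", "delighted", "neutral"]

    def test_maps_survey_wordings_to_tokens(self, tmp_path):
        path = _write_long(tmp_path, [
            'r1,a,I would be very pleased,That would really bother me,very important',
        ])
        data = read_survey(path)
        rec = data.records.iloc[0]
        assert (rec["functional"], rec["dysfunctional"]) == ("delighted", "dislike")
        assert rec["relevance"] == "very_important"

    def test_empty_cells_become_absent(self, tmp_path):
        path = _write_long(tmp_path, ["r1,a,expected,,NA"])
        rec = read_survey(path).records.iloc[0]
        assert rec["dysfunctional"] is None
        assert rec["relevance"] is None

    def test_unmappable_answer_reports_row(self, tmp_path):
        path = _write_long(tmp_path, [
            "r1,a,expected,dislike,important",
            "r2,a,maybe,dislike,important",
        ])
        with pytest.raises(ParseError, match="row 3.*maybe"):
            read_survey(path)

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("respondent_id,attribute_id,functional,relevance\nr1,a,expected,important\n")
        with pytest.raises(SchemaError, match="dysfunctional"):
            read_survey(path)

    def test_schema_renames_and_strata(self, tmp_path):
        path = tmp_path / "renamed.csv"
        path.write_text(
            "pid,item,f,d,rel,sex\nr1,a,expected,dislike,important,female\n")
        data = read_survey(path, schema={
            "respondent_id": "pid", "attribute_id": "item", "functional": "f",
            "dysfunctional": "d", "relevance": "rel", "strata": {"gender": "sex"},
        })
        assert data.strata_labels == ["gender"]
        assert data.records.loc[0, "gender"] == "female"

    def test_custom_levels_mapping(self, tmp_path):
        path = _write_long(tmp_path, ["r1,a,Setze ich voraus,dislike,important"])
        data = read_survey(path, schema={"levels": {"Setze ich voraus": "expected"}})
        assert data.records.loc[0, "functional"] == "expected"

    def test_panel_size_bookkeeping(self, reference_profiles_a, tmp_path):
        from kanosight import synth

        data = synth.generate_survey(reference_profiles_a, 382, seed=1)
        assert data.n_respondents == 382
        assert len(data.attributes) == 9

    def test_roundtrip_preserves_levels_exactly(self, small_panel, tmp_path):
        path = tmp_path / "roundtrip.csv"
        small_panel.to_csv(path)
        back = read_survey(path, schema={"strata": {"gender": "gender"}})
        pd.testing.assert_frame_equal(
            back.records.sort_values(["respondent_id", "attribute_id"]).reset_index(drop=True),
            small_panel.records.sort_values(["respondent_id", "attribute_id"]).reset_index(drop=True),
        )


class TestWideFormat:
    def test_wide_reader_matches_long(self, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text(
            "respondent_id,a_functional,a_dysfunctional,a_relevance,sex\n"
            "r1,expected,dislike,important,male\n"
            "r2,delighted,expected,very_important,female\n")
        data = read_survey_wide(path, attributes=["a"], strata={"gender": "sex"})
        assert data.n_respondents == 2
        assert list(data.records["functional"]) == ["expected", "delighted"]
        assert list(data.records["gender"]) == ["male", "female"]

    def test_absent_column_yields_absent_answers(self):
        frame = pd.DataFrame({"respondent_id": ["r1"], "a_functional": ["expected"],
                              "a_dysfunctional": ["dislike"]})
        long = wide_to_long(frame, ["a"])
        assert long.loc[0, "relevance"] is None


class TestDatasetValidation:
    def test_duplicate_respondent_attribute_rejected(self):
        frame = pd.DataFrame({
            "respondent_id": ["r1", "r1"], "attribute_id": ["a", "a"],
            "functional": ["expected"] * 2, "dysfunctional": ["dislike"] * 2,
            "relevance": ["important"] * 2,
        })
        with pytest.raises(KanosightError, match="duplicate"):
            SurveyDataset(frame)

    def test_unknown_attribute_in_list_rejected(self, tiny_dataset):
        with pytest.raises(KanosightError, match="not in the attribute list"):
            SurveyDataset(tiny_dataset.records, attributes=["alpha"])


class TestSplitGroups:
    def test_even_split_382_gives_191_191(self, reference_profiles_a):
        from kanosight import synth

        data = synth.generate_survey(reference_profiles_a, 382, seed=5)
        a, b = split_groups(data, 0.5, seed=11)
        assert (a.n_respondents, b.n_respondents) == (191, 191)

    def test_odd_split_rounds_group_a_up(self, reference_profiles_a):
        from kanosight import synth

        data = synth.generate_survey(reference_profiles_a, 5, seed=5)
        a, b = split_groups(data, 0.5, seed=11)
        assert (a.n_respondents, b.n_respondents) == (3, 2)

    def test_same_seed_same_partition(self, small_panel):
        a1, _ = split_groups(small_panel, 0.5, seed=42)
        a2, _ = split_groups(small_panel, 0.5, seed=42)
        assert set(a1.respondents) == set(a2.respondents)

    @given(fraction=st.floats(0.05, 0.95), seed=st.integers(0, 2**16))
    def test_split_is_a_partition(self, small_panel, fraction, seed):
        a, b = split_groups(small_panel, fraction, seed=seed)
        assert set(a.respondents) | set(b.respondents) == set(small_panel.respondents)
        assert not set(a.respondents) & set(b.respondents)
        assert a.n_respondents + b.n_respondents == small_panel.n_respondents

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, small_panel, fraction):
        with pytest.raises(KanosightError):
            split_groups(small_panel, fraction, seed=1)


class TestStratify:
    def test_partitions_respondents(self, small_panel):
        strata = stratify(small_panel, "gender")
        ids = [set(s.respondents) for s in strata.values()]
        assert set().union(*ids) == set(small_panel.respondents)
        assert sum(len(i) for i in ids) == small_panel.n_respondents

    def test_aggregation_collapses_values(self, tiny_dataset):
        strata = stratify(tiny_dataset, "gender",
                          {"female": "f", "male": "m"})
        assert set(strata) == {"f", "m"}
        assert strata["f"].n_respondents == 1

    def test_empty_aggregation_puts_everyone_unmapped(self, tiny_dataset):
        strata = stratify(tiny_dataset, "gender", {})
        assert set(strata) == {"unmapped"}
        assert strata["unmapped"].n_respondents == 3

    def test_unknown_label_raises_keyerror(self, tiny_dataset):
        with pytest.raises(KeyError):
            stratify(tiny_dataset, "shoe_size")
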