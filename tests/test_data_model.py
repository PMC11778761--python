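import numpy as np
import pandas as pd
import pytest

from zoipanc.data_model import (
    ANALYSIS_COLUMNS,
    DESIGN_COLUMNS,
    RAW_COLUMNS,
    SchemaError,
    build_design_matrix,
    complete_case_filter,
    lift_to_raw,
    recode_covariates,
    validate_dataset,
)
from zoipanc.simulate import SyntheticConfig, generate_pooled_dataset

from conftest import make_records

RAW_BASE = dict(
    sanc_visits=2, survey_year="2011", residence="urban", maternal_age="<20",
    maternal_edu="none", paternal_edu="none", wealth5="middle",
    birth_order="first", working="non_working",
    media_newspaper="not_at_all", media_tv="not_at_all", media_radio="not_at_all",
    decision_health="no", decision_purchases="no", decision_visits="no",
    beat_argue="no", beat_neglect="no", beat_goout="no", beat_refuse="no",
    beat_burn="no", wanted3="no_more", terminated_pregnancy="no")


def raw_records(*overrides):
    return pd.DataFrame([{**RAW_BASE, **ov} for ov in (overrides or ({},))])


class TestRecode:
    @pytest.mark.parametrize("source,target", [
        ("poorest", "poor"), ("poorer", "poor"), ("middle", "middle"),
        ("richer", "rich"), ("richest", "rich")])
    def test_wealth_merge(self, source, target):
        out = recode_covariates(raw_records({"wealth5": source}))
        assert out.loc[0, "wealth"] == target

    def test_media_weekly_threshold(self):
        below = {k: "less_than_weekly" for k in
                 ("media_newspaper", "media_tv", "media_radio")}
        out = recode_covariates(raw_records(
            below, {**below, "media_radio": "at_least_weekly"}))
        assert list(out["media"]) == ["non_exposed", "exposed"]

    def test_violence_opinion_any_reason(self):
        out = recode_covariates(raw_records({"beat_burn": "yes"}, {}))
        assert list(out["violence_opinion"]) == ["justified", "non_justified"]

    def test_decision_any_of_three(self):
        out = recode_covariates(raw_records({"decision_visits": "yes"}))
        assert out.loc[0, "decision"] == "yes"

    @pytest.mark.parametrize("source,target", [
        ("then", "yes"), ("later", "yes"), ("no_more", "no")])
    def test_wanted_pregnancy_merge(self, source, target):
        out = recode_covariates(raw_records({"wanted3": source}))
        assert out.loc[0, "wanted_pregnancy"] == target

    def test_missing_propagates_unless_determined(self):
        out = recode_covariates(raw_records(
            {"media_tv": pd.NA},                                  # undecidable
            {"media_tv": pd.NA, "media_radio": "at_least_weekly"},  # decided
            {"wealth5": pd.NA}))
        assert pd.isna(out.loc[0, "media"])
        assert out.loc[1, "media"] == "exposed"
        assert pd.isna(out.loc[2, "wealth"])

    def test_unknown_source_level_names_field(self):
        with pytest.raises(SchemaError, match="wealth5"):
            recode_covariates(raw_records({"wealth5": "affluent"}))

    def test_idempotent_through_lift(self):
        cfg = SyntheticConfig(seed=42, n_per_year={"2011": 80, "2014": 60,
                                                   "2017-18": 60, "2022": 60})
        df, _ = generate_pooled_dataset(cfg)
        again = recode_covariates(lift_to_raw(df))
        pd.testing.assert_frame_equal(again.astype(object), df.astype(object))


class TestCompleteCaseFilter:
    def test_drops_rows_with_missing(self):
        df = make_records({}, {"wealth": pd.NA}, {"sanc_visits": 3},
                          {"wealth": pd.NA}, {"media": "exposed"})
        kept, dropped = complete_case_filter(df)
        assert (len(kept), dropped) == (3, 2)
        assert list(kept["sanc_visits"]) == [0, 3, 0]  # order preserved

    def test_identity_when_complete(self):
        df = make_records({}, {"sanc_visits": 2})
        kept, dropped = complete_case_filter(df)
        assert dropped == 0
        pd.testing.assert_frame_equal(kept, df)


class TestValidate:
    def test_missing_required_column(self, tmp_path):
        df = make_records({}).drop(columns=["sanc_visits"])
        with pytest.raises(SchemaError, match="sanc_visits"):
            validate_dataset(df)

    def test_non_integer_outcome(self):
        with pytest.raises(SchemaError, match="non-negative integer"):
            validate_dataset(make_records({"sanc_visits": "3.5"}))

    def test_unknown_level_lists_offender(self):
        with pytest.raises(SchemaError, match="residence"):
            validate_dataset(make_records({"residence": "suburban"}))

    def test_small_fixture_roundtrip(self, tmp_path):
        df = make_records(*[{"sanc_visits": i} for i in range(10)])
        path = tmp_path / "records.csv"
        df.to_csv(path, index=False)
        out = validate_dataset(path)
        assert len(out) == 10
        assert list(out.columns) == ANALYSIS_COLUMNS
        assert list(out["sanc_visits"]) == list(range(10))

    def test_en_dash_year_canonicalised(self):
        out = validate_dataset(make_records({"survey_year": "2017–18"}))
        assert out.loc[0, "survey_year"] == "2017-18"

    def test_missing_tokens_normalised(self):
        out = validate_dataset(make_records({"wealth": ""}, {"wealth": "NA"}))
        assert out["wealth"].isna().all()

    def test_raw_schema(self):
        out = validate_dataset(raw_records({}), raw=True)
        assert list(out.columns) == RAW_COLUMNS


class TestDesignMatrix:
    def test_reference_profile_row(self):
        d = build_design_matrix(make_records({}))
        assert d.p == len(DESIGN_COLUMNS) == 22
        row = d.X[0]
        assert row[0] == 1.0
        assert np.all(row[1:-2] == 0.0)
        assert row[-2] == 1.0   # year code for 2011
        assert row[-1] == 0.0   # urban: no interaction

    def test_rural_2022_interaction_cell(self):
        d = build_design_matrix(make_records(
            {"residence": "rural", "survey_year": "2022"}))
        assert d.X[0, -2] == 4.0
        assert d.X[0, -1] == 4.0

    def test_one_hot_difference(self):
        d = build_design_matrix(make_records(
            {"maternal_edu": "primary"}, {"maternal_edu": "higher"}))
        diff = np.flatnonzero(d.X[0] != d.X[1])
        labels = [d.column_labels[j] for j in diff]
        assert sorted(labels) == ["maternal_edu[higher]", "maternal_edu[primary]"]

    def test_dummy_blocks_sum_at_most_one(self, small_df):
        d = build_design_matrix(small_df.head(200))
        blocks = {}
        for j, label in enumerate(d.column_labels[1:-2], start=1):
            blocks.setdefault(label.split("[")[0], []).append(j)
        for cols in blocks.values():
            assert np.all(d.X[:, cols].sum(axis=1) <= 1)

    def test_row_count_matches_records(self, small_df):
        d = build_design_matrix(small_df)
        assert d.n == len(small_df) == len(d.y)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_design_matrix(make_records({}).iloc[:0])

    def test_incomplete_cases_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            build_design_matrix(make_records({"wealth": pd.NA}))

    def test_reference_map_holds_first_levels(self):
        d = build_design_matrix(make_records({}))
        assert d.reference_map["residence"] == "urban"
        assert d.reference_map["maternal_edu"] == "none"
        assert d.reference_map["working"] == "non_working"
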