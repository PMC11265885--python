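"""Instrument schema, recoding and response-table validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sees
from sees.instrument import (
    Instrument,
    RecodeError,
    ResponseTable,
    SchemaError,
    SurveyItem,
    recode_responses,
    validate_responses,
)


class TestPackagedInstrument:
    def test_scored_item_count(self, instrument):
        assert len(instrument.scored_items) == 18

    def test_subscale_sizes(self, instrument):
        assert len(instrument.subscale_items("subjective_evidence")) == 8
        assert len(instrument.subscale_items("methodological_appropriateness")) == 10
        assert len(instrument.subscale_items("prior")) == 1

    def test_reverse_coded_set(self, instrument):
        assert instrument.reverse_coded_ids == {"SE_4", "SE_5", "SE_6", "SE_7"}

    def test_four_categories_and_na(self, instrument):
        assert instrument.C == 4
        assert all(it.allows_na for it in instrument.scored_items)
        assert all(it.n_categories == 4 for it in instrument.items)

    def test_item_texts_present(self, instrument):
        assert all(it.text for it in instrument.items)
        # every scored item carries an illustrative example
        assert all(it.example for it in instrument.scored_items)


def _item(id="SE_1", subscale="subjective_evidence", C=4, **kw):
    defaults = dict(
        label="x", text="t", example="", reverse_coded=False, allows_na=True,
        response_labels=tuple(f"l{i}" for i in range(C)),
    )
    defaults.update(kw)
    return SurveyItem(id=id, subscale=subscale, **defaults)


class TestSchemaValidation:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(SchemaError, match="duplicate"):
            Instrument(items=(_item(), _item()))

    def test_wrong_category_count_rejected(self):
        with pytest.raises(SchemaError, match="SE_1"):
            Instrument(items=(_item(C=3),), C=4)

    def test_unknown_subscale_rejected(self):
        with pytest.raises(SchemaError, match="subscale"):
            Instrument(items=(_item(subscale="bogus"),))

    def test_prefix_mismatch_rejected(self):
        with pytest.raises(SchemaError, match="prefix"):
            Instrument(items=(_item(id="MA_1", subscale="subjective_evidence"),))


class TestRecode:
    @pytest.mark.parametrize(
        "item_id,label,expected",
        [
            ("SE_1", "yes, definitely", 4),
            ("SE_1", "no, definitely not", 1),
            ("SE_4", "yes, definitely", 1),       # counter-indicative
            ("SE_4", "no, definitely not", 4),
            ("MA_3", "no concerns", 4),
            ("MA_3", "major concerns", 1),
        ],
    )
    def test_label_coding(self, instrument, item_id, label, expected):
        raw = pd.DataFrame({"team_id": ["t1"], item_id: [label]})
        table = recode_responses(raw, instrument)
        assert table.values[0, 0] == expected

    def test_na_label_becomes_missing(self, instrument):
        raw = pd.DataFrame(
            {"team_id": ["t1", "t2"],
             "MA_3": ["not applicable/I do not know", "no concerns"]}
        )
        table = recode_responses(raw, instrument)
        assert np.isnan(table.values[0, 0])
        assert table.na_counts["MA_3"] == 1

    def test_label_matching_tolerates_dialects(self, instrument):
        raw = pd.DataFrame({"team_id": ["t1"], "SE_1": ["  Yes  definitely! "]})
        assert recode_responses(raw, instrument).values[0, 0] == 4

    def test_integer_codes_accepted_as_coded(self, instrument):
        # integers are final codes: no second reversal on SE_4
        raw = pd.DataFrame({"team_id": ["t1"], "SE_4": [4]})
        assert recode_responses(raw, instrument).values[0, 0] == 4

    def test_unrecognized_label_names_cell(self, instrument):
        raw = pd.DataFrame({"team_id": ["t1"], "SE_1": ["maybe"]})
        with pytest.raises(RecodeError, match=r"row 0.*SE_1"):
            recode_responses(raw, instrument)

    def test_out_of_range_integer_rejected(self, instrument):
        raw = pd.DataFrame({"team_id": ["t1"], "SE_1": [7]})
        with pytest.raises(RecodeError, match="out of range"):
            recode_responses(raw, instrument)

    def test_roundtrip_label_lookup(self, instrument):
        labels = ["yes, definitely", "no, mostly not", "yes, mostly"]
        raw = pd.DataFrame({"team_id": ["a", "b", "c"], "SE_4": labels})
        table = recode_responses(raw, instrument)
        item = instrument["SE_4"]
        back = [item.coded_labels()[int(v) - 1] for v in table.values[:, 0]]
        assert back == labels

    @settings(max_examples=100, deadline=None)
    @given(x=st.integers(1, 7), C=st.integers(2, 7))
    def test_reverse_coding_is_involution(self, x, C):
        if x > C:
            x = C
        assert C + 1 - (C + 1 - x) == x


class TestValidate:
    def _table(self, values, C=4):
        values = np.asarray(values, dtype=float)
        return ResponseTable(
            team_ids=[f"t{i}" for i in range(values.shape[0])],
            item_ids=[f"SE_{j+1}" for j in range(values.shape[1])],
            values=values,
            C=C,
        )

    def test_out_of_range_flagged(self, instrument):
        table = self._table([[5.0, 2.0], [1.0, 3.0]])
        report = validate_responses(table, instrument)
        assert len(report.range_violations) == 1
        assert report.range_violations[0][1] == "SE_1"
        assert not report.ok

    def test_high_na_flag_on_ten_team_table(self, instrument):
        col = [1.0] * 4 + [np.nan] * 6        # 60% missing
        table = self._table(np.column_stack([col, [2.0] * 10]))
        report = validate_responses(table, instrument)
        assert report.na_fraction["SE_1"] == pytest.approx(0.6)
        assert report.high_na_items == ["SE_1"]

    def test_clean_table_has_empty_report(self, instrument):
        table = self._table([[1.0, 4.0], [2.0, 3.0]])
        report = validate_responses(table, instrument)
        assert report.ok
        assert report.range_violations == []
        assert report.high_na_items == []

    def test_all_missing_rows_and_columns(self, instrument):
        table = self._table([[np.nan, 1.0], [np.nan, np.nan]])
        report = validate_responses(table, instrument)
        assert report.all_missing_items == ["SE_1"]
        assert report.all_missing_teams == ["t1"]
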