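"""Scoring, listwise deletion, and prevalence classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import symptomnet as sn
from symptomnet.scales import (
    EmptyCohortError,
    ExclusionReport,
    PrevalenceReport,
    SchemaError,
)


def _full_table(n, fill_mbi=0, fill_phq=0, index_start=0):
    cols = {f"MBI{i}": fill_mbi for i in range(1, 16)}
    cols.update({f"PHQ{i}": fill_phq for i in range(1, 10)})
    return pd.DataFrame(cols, index=range(index_start, index_start + n), dtype=float)


class TestValidation:
    def test_listwise_deletion_matches_study_flow(self):
        """636 completed surveys, 20 with a missing item -> 616 kept, 97% retention."""
        df = _full_table(636, fill_mbi=2, fill_phq=1)
        df.iloc[:20, 0] = np.nan
        rm = sn.ResponseMatrix.from_dataframe(df)
        clean, report = sn.validate_responses(rm)
        assert clean.n_respondents == 616
        assert report.n_input == 636
        assert sorted(report.dropped_ids) == list(range(20))
        assert report.retention_percent == 97

    def test_complete_matrix_is_untouched(self):
        df = _full_table(5, fill_mbi=3, fill_phq=2)
        clean, report = sn.validate_responses(sn.ResponseMatrix.from_dataframe(df))
        assert report.dropped_ids == ()
        assert clean.n_respondents == 5
        pd.testing.assert_frame_equal(clean.data, df)

    def test_all_respondents_missing_raises_empty_cohort(self):
        df = _full_table(1)
        df.loc[0, "PHQ3"] = np.nan
        with pytest.raises(EmptyCohortError):
            sn.validate_responses(sn.ResponseMatrix.from_dataframe(df))

    def test_unknown_item_label_is_schema_error(self):
        df = _full_table(3)
        df["XXX1"] = 0.0
        with pytest.raises(SchemaError):
            sn.ResponseMatrix.from_dataframe(df)

    def test_out_of_bounds_value_rejected(self):
        df = _full_table(3)
        df.loc[0, "PHQ1"] = 5  # PHQ items top out at 3
        with pytest.raises(SchemaError):
            sn.ResponseMatrix.from_dataframe(df)


class TestScoring:
    def test_bounds_of_mbi_totals(self):
        lo = sn.ResponseMatrix.from_dataframe(_full_table(1, fill_mbi=0))
        hi = sn.ResponseMatrix.from_dataframe(_full_table(1, fill_mbi=6))
        assert sn.score_totals(lo, sn.MBI_GS).iloc[0] == 0
        assert sn.score_totals(hi, sn.MBI_GS).iloc[0] == 90

    def test_phq_total_five_screens_positive(self):
        df = _full_table(1)
        for item, v in zip([f"PHQ{i}" for i in range(1, 10)], [1, 1, 1, 1, 1, 0, 0, 0, 0]):
            df[item] = float(v)
        rm = sn.ResponseMatrix.from_dataframe(df)
        totals = sn.score_totals(rm, sn.PHQ9)
        assert totals.iloc[0] == 5
        assert sn.PHQ9.is_positive(totals.iloc[0])

    def test_burnout_cutoff_is_strict(self):
        assert not sn.MBI_GS.is_positive(34)
        assert sn.MBI_GS.is_positive(35)

    def test_reverse_scoring_maps_to_complement(self):
        scale = sn.ScaleDefinition(
            scale_id="mbi_rev",
            item_ids=sn.MBI_GS.item_ids,
            category_min=0,
            category_max=6,
            cutoff_value=34,
            reverse_items=frozenset({f"MBI{i}" for i in range(10, 16)}),
        )
        df = _full_table(1, fill_mbi=6)
        totals = sn.score_totals(sn.ResponseMatrix.from_dataframe(df), scale)
        assert totals.iloc[0] == 9 * 6  # six reversed items contribute 0

    @given(st.integers(0, 6))
    def test_reversal_is_an_involution(self, x):
        assert 6 - (6 - x) == x

    def test_monotone_in_any_nonreversed_item(self):
        df = _full_table(1, fill_mbi=2)
        base = sn.score_totals(sn.ResponseMatrix.from_dataframe(df), sn.MBI_GS).iloc[0]
        df.loc[0, "MBI7"] = 3
        bumped = sn.score_totals(sn.ResponseMatrix.from_dataframe(df), sn.MBI_GS).iloc[0]
        assert bumped > base


class TestPrevalence:
    @pytest.mark.parametrize(
        "n_pos, n_total, expected",
        [(297, 616, 48.2), (395, 616, 64.1), (0, 616, 0.0)],
    )
    def test_percent_rounding(self, n_pos, n_total, expected):
        rep = PrevalenceReport(scale_id="x", n_total=n_total, n_positive=n_pos)
        assert rep.percent == expected

    def test_prevalence_counts_against_cutoffs(self):
        totals = [35] * 297 + [34] * (616 - 297)
        rep = sn.prevalence(totals, sn.MBI_GS)
        assert (rep.n_positive, rep.percent) == (297, 48.2)
        totals = [5] * 395 + [4] * (616 - 395)
        rep = sn.prevalence(totals, sn.PHQ9)
        assert (rep.n_positive, rep.percent) == (395, 64.1)

    @given(st.lists(st.integers(0, 90), min_size=1, max_size=60), st.randoms())
    def test_invariant_under_respondent_reordering(self, totals, rnd):
        shuffled = list(totals)
        rnd.shuffle(shuffled)
        a = sn.prevalence(totals, sn.MBI_GS)
        b = sn.prevalence(shuffled, sn.MBI_GS)
        assert a.n_positive == b.n_positive and a.percent == b.percent

    def test_empty_totals_rejected(self):
        with pytest.raises(ValueError):
            sn.prevalence([], sn.PHQ9)

    def test_retention_rounds_half_up(self):
        assert ExclusionReport(n_input=636, n_retained=616, dropped_ids=()).retention_percent == 97


class TestIO:
    def test_csv_round_trip_with_missing(self, tmp_path):
        df = _full_table(4, fill_mbi=1, fill_phq=2)
        df.loc[2, "MBI5"] = np.nan
        rm = sn.ResponseMatrix(data=df, bounds={c: (0, 6) if c.startswith("MBI") else (0, 3) for c in df.columns})
        path = tmp_path / "resp.csv"
        sn.write_responses_csv(rm, path)
        back = sn.read_responses_csv(path)
        assert back.data.isna().sum().sum() == 1
        assert np.isnan(back.data.loc[2, "MBI5"])

    def test_scale_definition_config_round_trip(self):
        d = sn.PHQ9.to_dict()
        assert sn.ScaleDefinition.from_dict(d) == sn.PHQ9
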