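import datetime as dt
import io

import numpy as np
import pandas as pd
import pytest

from seasonscan import registry, synthetic
from seasonscan.registry import (CaseFormatError, CohortSpec, age_at_diagnosis_months,
                                 aggregate_counts, assign_period, filter_cases,
                                 read_cases, write_cases)

VALID_CSV = """case_id,group,sex,birth_date,diagnosis_date,laterality,stage,mycn
a1,neuroblastoma,M,2004-03-10,2005-09-09,,localised,amplified
a2,retinoblastoma,F,2010-01-01,2010-06-15,bilateral,,
a3,nephroblastoma,F,2002-12-31,2006-02-28,,,
"""


def _read(text, **kw):
    return read_cases(io.StringIO(text), **kw)


class TestReadCases:
    def test_valid_rows_survive(self):
        cases = _read(VALID_CSV)
        assert len(cases) == 3
        assert cases.loc[0, "birth_date"] == dt.date(2004, 3, 10)
        assert cases.loc[1, "stage"] is None

    def test_missing_column_is_a_format_error(self):
        bad = VALID_CSV.replace("diagnosis_date,", "ddate,")
        with pytest.raises(CaseFormatError, match="diagnosis_date"):
            _read(bad)

    @pytest.mark.parametrize("row, rule", [
        ("x,neuroblastoma,M,2005-09-09,2004-03-10,,,", "precedes"),
        ("x,neuroblastoma,M,2000-01-01,2015-01-01,,,", "15 years"),
        ("x,carcinoma,M,2004-03-10,2005-09-09,,,", "unknown diagnostic group"),
        ("x,neuroblastoma,M,2004-13-10,2005-09-09,,,", "birth_date"),
        ("x,nephroblastoma,M,2004-03-10,2005-09-09,,localised,", "stage recorded"),
        ("x,neuroblastoma,M,2004-03-10,2005-09-09,unilateral,,", "laterality recorded"),
    ])
    def test_invalid_row_rejected_with_named_rule(self, row, rule):
        with pytest.raises(ValueError, match=rule):
            _read(VALID_CSV + row + "\n", on_invalid="error")
        kept = _read(VALID_CSV + row + "\n", on_invalid="ignore")
        assert len(kept) == 3

    def test_write_read_round_trip(self, tmp_path):
        cfg = synthetic.SyntheticConfig(seed=7)
        table = synthetic.generate_cases(cfg)
        path = tmp_path / "cases.csv"
        write_cases(table, path)
        back = read_cases(path, on_invalid="error")
        pd.testing.assert_frame_equal(back, table.reset_index(drop=True))


class TestAgeAtDiagnosis:
    @pytest.mark.parametrize("birth, diag, months", [
        ((2004, 3, 10), (2004, 3, 10), 0),
        ((2004, 3, 10), (2005, 9, 10), 18),
        ((2004, 3, 10), (2005, 9, 9), 17),
        ((2004, 1, 31), (2004, 2, 29), 1),   # clamped month-end counts as reached
        ((2004, 1, 31), (2004, 3, 1), 1),
        ((2000, 6, 15), (2015, 6, 14), 179),
    ])
    def test_completed_months(self, birth, diag, months):
        assert age_at_diagnosis_months(dt.date(*birth), dt.date(*diag)) == months

    @pytest.mark.parametrize("birth", [dt.date(2004, 3, 10), dt.date(2003, 12, 31),
                                       dt.date(2004, 2, 29)])
    def test_day_count_oracle_over_a_calendar_span(self, birth):
        # independent oracle: dateutil's normalised calendar arithmetic
        from dateutil.relativedelta import relativedelta
        for offset in range(0, 800, 7):
            day = birth + dt.timedelta(days=offset)
            delta = relativedelta(day, birth)
            assert age_at_diagnosis_months(birth, day) == delta.years * 12 + delta.months

    def test_reversed_dates_raise(self):
        with pytest.raises(ValueError):
            age_at_diagnosis_months(dt.date(2005, 1, 1), dt.date(2004, 1, 1))


class TestAssignPeriod:
    @pytest.mark.parametrize("date, scheme, expected", [
        ((2005, 1, 31), "calendar", (1, 2005)),
        ((2005, 1, 15), "midmonth", (1, 2005)),
        ((2005, 1, 14), "midmonth", (12, 2004)),
        ((2005, 12, 15), "midmonth", (12, 2005)),
        ((2005, 12, 31), "midmonth", (12, 2005)),
        ((2005, 7, 14), "midmonth", (6, 2005)),
    ])
    def test_period_assignment(self, date, scheme, expected):
        assert assign_period(dt.date(*date), scheme) == expected

    def test_unknown_scheme_raises(self):
        with pytest.raises(ValueError):
            assign_period(dt.date(2005, 1, 1), "weekly")


class TestAggregateCounts:
    def test_single_case_lands_in_its_cell(self):
        cases = _read(
            "case_id,group,sex,birth_date,diagnosis_date,laterality,stage,mycn\n"
            "a,neuroblastoma,M,2002-01-01,2003-08-02,,,\n")
        spec = CohortSpec(group="neuroblastoma", axis="diagnosis")
        out = aggregate_counts(cases, spec).set_index(["year", "period"])["observed"]
        assert out.loc[(2003, 8)] == 1
        assert out.sum() == 1

    def test_partition_additivity_by_sex(self, null_cases):
        base = CohortSpec(group="neuroblastoma", axis="birth")
        total = aggregate_counts(null_cases, base)["observed"]
        parts = sum(
            aggregate_counts(null_cases, CohortSpec(group="neuroblastoma",
                                                    sex=s, axis="birth"))["observed"]
            for s in ("M", "F"))
        assert (total == parts).all()

    def test_partition_additivity_by_age_cutoff(self, null_cases):
        base = CohortSpec(group="neuroblastoma", axis="diagnosis")
        total = aggregate_counts(null_cases, base)["observed"]
        young = CohortSpec(group="neuroblastoma", axis="diagnosis",
                           age_cutoff_months=18, age_side="le")
        old = CohortSpec(group="neuroblastoma", axis="diagnosis",
                         age_cutoff_months=18, age_side="gt")
        parts = (aggregate_counts(null_cases, young)["observed"]
                 + aggregate_counts(null_cases, old)["observed"])
        assert (total == parts).all()

    def test_scheme_totals_agree_but_margins_differ(self, null_cases):
        spec = CohortSpec(group="neuroblastoma", axis="diagnosis")
        import warnings
        cal = aggregate_counts(null_cases, spec, "calendar")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # wrap-around clamp warning is data-dependent
            mid = aggregate_counts(null_cases, spec, "midmonth")
        assert cal["observed"].sum() == mid["observed"].sum()
        cal_margin = cal.groupby("period")["observed"].sum()
        mid_margin = mid.groupby("period")["observed"].sum()
        assert (cal_margin != mid_margin).any()

    def test_midmonth_agrees_with_bruteforce_rebinning(self, null_cases):
        spec = CohortSpec(group="neuroblastoma", axis="diagnosis")
        mid = aggregate_counts(null_cases, spec, "midmonth")
        margins = mid.groupby("period")["observed"].sum()
        # independent oracle: shift each date back 14 days, take that month
        kept = filter_cases(null_cases, spec)
        # shifting any date back 14 days lands it in its midmonth period's month
        shifted = [(d - dt.timedelta(days=14)).month
                   for d in kept["diagnosis_date"]]
        oracle = pd.Series(shifted).value_counts().reindex(range(1, 13), fill_value=0)
        assert (margins.to_numpy() == oracle.to_numpy()).all()

    def test_empty_cohort_warns_but_returns_grid(self, null_cases):
        spec = CohortSpec(group="hepatoblastoma", axis="diagnosis")
        with pytest.warns(UserWarning, match="no cases"):
            out = aggregate_counts(null_cases, spec)
        assert out["observed"].sum() == 0
        assert len(out) == 16 * 12
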