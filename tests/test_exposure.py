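import numpy as np
import pandas as pd
import pytest

from seasonscan import exposure, synthetic
from seasonscan.exposure import (birth_cohort_person_years, census_person_years,
                                 expected_counts, reference_rates, time_at_risk)
from seasonscan.series import OESeries, collapse_to_loop


class TestTimeAtRisk:
    @pytest.mark.parametrize("m, y, a, expected", [
        (7, 2010, 3, 1.0),            # follow-up still running
        (7, 2012, 3, 5.5 / 12),       # final year: (12 - 7 + 0.5)/12
        (1, 2015, 1, 0.0),            # beyond the follow-up end
        (12, 2015, 0, 0.5 / 12),      # born December of the last year
    ])
    def test_values(self, m, y, a, expected):
        assert time_at_risk(m, y, a, end_year=2015) == pytest.approx(expected)

    def test_age_beyond_fifteenth_birthday_raises(self):
        with pytest.raises(ValueError, match="15th birthday"):
            time_at_risk(1, 2000, 15)


class TestBirthCohortPersonYears:
    @pytest.fixture(scope="class")
    def py(self):
        births = synthetic.generate_births(synthetic.SyntheticConfig(births_per_month=100.0))
        return birth_cohort_person_years(births, end_year=2015)

    def test_full_year_cell(self, py):
        cell = py.query("month == 3 and year == 2000 and age == 5")["py"]
        assert float(cell.iloc[0]) == pytest.approx(100.0)

    def test_final_cohort_contributes_half_a_month(self, py):
        cell = py.query("month == 12 and year == 2015 and age == 0")["py"]
        assert float(cell.iloc[0]) == pytest.approx(100.0 * 0.5 / 12)

    def test_each_birth_contributes_the_capped_follow_up(self, py):
        # summation oracle: a child born (m, y) is at risk for 15 years or
        # until end of 2015, whichever comes first under the mid-month rule
        total_by_cohort = py.groupby(["month", "year"])["py"].sum() / 100.0
        for (m, y), got in total_by_cohort.items():
            if y + 14 < 2015:
                want = 15.0
            else:
                want = (2015 - y) + (12 - m + 0.5) / 12
            assert got == pytest.approx(want), (m, y)

    def test_negative_births_rejected(self):
        births = synthetic.generate_births(synthetic.SyntheticConfig())
        births.loc[0, "n_births"] = -1
        with pytest.raises(ValueError, match="non-negative"):
            birth_cohort_person_years(births)


class TestCensusPersonYears:
    def test_leap_february_share(self):
        census = pd.DataFrame({"year": sorted([2004, 2005] * 15),
                               "age": list(range(15)) * 2,
                               "population": [100.0] * 15 + [120.0] * 15})
        py = census_person_years(census, (2004, 2004))
        feb = py.query("month == 2 and age == 3")["py"]
        assert float(feb.iloc[0]) == pytest.approx(110.0 * 29 / 366)

    def test_monthly_shares_reconstitute_annual(self):
        cfg = synthetic.SyntheticConfig()
        py = census_person_years(synthetic.generate_census(cfg), cfg.study_years)
        monthly = py.groupby(["year", "age"])["py"].sum()
        annual = py.groupby(["year", "age"])["py_annual"].first()
        assert np.allclose(monthly, annual, rtol=1e-12)

    def test_missing_following_january_raises(self):
        census = pd.DataFrame({"year": [2004] * 15, "age": range(15),
                               "population": 100.0})
        with pytest.raises(ValueError, match="2005"):
            census_person_years(census, (2004, 2004))


class TestRatesAndExpected:
    @pytest.fixture(scope="class")
    def py(self):
        cfg = synthetic.SyntheticConfig()
        return census_person_years(synthetic.generate_census(cfg), cfg.study_years)

    def test_pooled_rate_is_cases_over_person_years(self, py):
        cases = pd.Series([36] + [0] * 14, index=pd.RangeIndex(15, name="age"))
        total_py0 = py.query("age == 0")["py"].sum()
        rates = reference_rates(cases, py, mode="pooled")
        assert rates.loc[0] == pytest.approx(36 / total_py0)
        assert (rates.loc[1:] == 0).all()

    def test_cases_without_exposure_raise(self, py):
        cases = pd.Series([1] * 15, index=pd.RangeIndex(15, name="age"))
        with pytest.raises(ValueError, match="zero person-years"):
            reference_rates(cases, py.query("age > 0"), mode="pooled")

    def test_internal_standardisation_matches_observed_total(self, py):
        rates = pd.Series(1e-5, index=pd.RangeIndex(15, name="age"), name="rate")
        e = expected_counts(rates, py, standardise=True, total_observed=1839)
        assert e["expected"].sum() == pytest.approx(1839, rel=1e-12)

    def test_expected_invariant_to_rate_rescaling_when_standardised(self, py):
        rates = pd.Series(np.linspace(1e-6, 3e-5, 15),
                          index=pd.RangeIndex(15, name="age"), name="rate")
        e1 = expected_counts(rates, py, standardise=True, total_observed=500)
        e2 = expected_counts(rates * 7.3, py, standardise=True, total_observed=500)
        assert np.allclose(e1["expected"], e2["expected"], rtol=1e-12)

    def test_uniform_inputs_give_day_length_proportional_expected(self, py):
        rates = pd.Series(1e-5, index=pd.RangeIndex(15, name="age"), name="rate")
        e = expected_counts(rates, py, standardise=False)
        by_month = e.query("year == 2001").set_index("period")["expected"]
        assert by_month.loc[1] / by_month.loc[2] == pytest.approx(31 / 28)
        assert by_month.loc[4] == pytest.approx(by_month.loc[6])


class TestCollapseToLoop:
    def test_single_year_grid_is_identity(self):
        tab = pd.DataFrame({"year": 2005, "period": range(1, 13),
                            "observed": range(12), "expected": np.ones(12)})
        loop = collapse_to_loop(tab)
        assert (loop.observed == np.arange(12)).all()

    def test_totals_are_conserved(self):
        rng = np.random.default_rng(5)
        tab = pd.DataFrame(
            [(y, p, rng.integers(0, 9), rng.uniform(0.5, 3))
             for y in range(2000, 2016) for p in range(1, 13)],
            columns=["year", "period", "observed", "expected"])
        loop = collapse_to_loop(tab)
        assert loop.total_observed == tab["observed"].sum()
        assert loop.total_expected == pytest.approx(tab["expected"].sum())

    def test_grid_mismatch_raises(self):
        tab = pd.DataFrame({"year": 2005, "period": [1, 1], "observed": [1, 2],
                            "expected": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            collapse_to_loop(tab)
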