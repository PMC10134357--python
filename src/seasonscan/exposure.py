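"""Person-years at risk and expected monthly case counts.

Two constructions are supported, mirroring how national population data come:

* **birth cohort** — monthly live-birth counts NB_{m,y}; the cohort born in
  month m of year y contributes, at completed age a, a time at risk
  T_{m,y,a} of one full year while a + y is before the follow-up end, the
  remaining (12 - m + 0.5)/12 of a year in the final calendar year (births
  are taken as uniform within their month, hence the half-month), and nothing
  afterwards. PY_{m,y,a} = NB_{m,y} * T_{m,y,a}.

* **census** — 1-January population counts POP_{y,a}; annual person-years are
  the two-year average PY_{y,a} = (POP_{y,a} + POP_{y+1,a}) / 2, split over
  months by their day counts (Gregorian leap rules).

Expected counts come from age-specific reference rates applied to the monthly
person-years; with internal standardisation the expected total is rescaled to
the observed total, so the monthly pattern alone carries the signal.
"""

from __future__ import annotations

import calendar

import numpy as np
import pandas as pd

from .series import N_PERIODS, OESeries, collapse_to_loop  # re-export for convenience

MAX_AGE = 14  # completed years; follow-up stops at the 15th birthday

__all__ = [
    "time_at_risk", "birth_cohort_person_years", "census_person_years",
    "reference_rates", "expected_counts", "collapse_to_loop",
    "days_in_month", "days_in_year", "read_births", "read_census",
]


def days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(year, month)[1]


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def time_at_risk(m: int, y: int, a: int, end_year: int = 2015) -> float:
    """Time at risk (years) at completed age ``a`` for the cohort born (m, y).

    1 while a + y is before ``end_year``; (12 - m + 0.5)/12 in the final year
    of follow-up; 0 beyond it.
    """
    if not 1 <= m <= 12:
        raise ValueError(f"month must be 1..12, got {m}")
    if not 0 <= a <= MAX_AGE:
        raise ValueError(f"age must be 0..{MAX_AGE} (follow-up stops at the "
                         f"15th birthday), got {a}")
    if a + y < end_year:
        return 1.0
    if a + y == end_year:
        return (12 - m + 0.5) / 12
    return 0.0


def read_births(path) -> pd.DataFrame:
    """Read a ``year,month,n_births`` CSV."""
    df = pd.read_csv(path)
    missing = {"year", "month", "n_births"} - set(df.columns)
    if missing:
        raise ValueError(f"births csv is missing columns: {sorted(missing)}")
    return df.loc[:, ["year", "month", "n_births"]]


def read_census(path) -> pd.DataFrame:
    """Read a ``year,age,population`` CSV."""
    df = pd.read_csv(path)
    missing = {"year", "age", "population"} - set(df.columns)
    if missing:
        raise ValueError(f"census csv is missing columns: {sorted(missing)}")
    return df.loc[:, ["year", "age", "population"]]


def _check_grid(df: pd.DataFrame, years: range, col2: str, values2: range, what: str) -> None:
    idx = pd.MultiIndex.from_product([years, values2], names=[df.columns[0], col2])
    have = pd.MultiIndex.from_frame(df.iloc[:, :2])
    missing = idx.difference(have)
    if len(missing):
        raise ValueError(f"{what} grid is incomplete; first missing cell: {missing[0]}")


def birth_cohort_person_years(births: pd.DataFrame,
                              end_year: int = 2015) -> pd.DataFrame:
    """Person-years by (month, year of birth, age) from monthly birth counts.

    Returns a long table ``month, year, age, time_at_risk, py`` tagged with
    ``attrs["construction"] = "birth_cohort"``. Cells with zero time at risk
    are retained so that downstream sums see a complete grid.
    """
    births = births.rename(columns={"n_births": "births"})
    if (births["births"] < 0).any():
        raise ValueError("birth counts must be non-negative")
    years = sorted(births["year"].unique())
    _check_grid(births[["year", "month", "births"]], years, "month", range(1, 13), "births")

    ages = np.arange(MAX_AGE + 1)
    rows = births.loc[births.index.repeat(len(ages))].reset_index(drop=True)
    rows["age"] = np.tile(ages, len(births))
    t = np.array([time_at_risk(m, y, a, end_year)
                  for m, y, a in zip(rows["month"], rows["year"], rows["age"])])
    rows["time_at_risk"] = t
    rows["py"] = rows["births"] * t
    out = rows.loc[:, ["month", "year", "age", "time_at_risk", "py"]]
    out.attrs["construction"] = "birth_cohort"
    out.attrs["end_year"] = end_year
    return out


def census_person_years(census: pd.DataFrame,
                        study_years: tuple[int, int]) -> pd.DataFrame:
    """Person-years by (month, year, age) from 1-January census counts.

    Annual PY_{y,a} is the mean of consecutive 1-January populations; monthly
    person-years weight it by the number of days in the month, so monthly
    shares reconstitute the annual total exactly.
    """
    if (census["population"] < 0).any():
        raise ValueError("census populations must be non-negative")
    lo, hi = study_years
    for y in range(lo, hi + 2):
        have = census.loc[census["year"] == y, "age"].unique()
        if not set(range(MAX_AGE + 1)) <= set(have):
            raise ValueError(f"census is missing ages for 1 January {y} "
                             "(the grid must extend one year past the study end)")
    pop = census.set_index(["year", "age"])["population"]
    rows = []
    for y in range(lo, hi + 1):
        nd_year = days_in_year(y)
        for a in range(MAX_AGE + 1):
            py_annual = (pop.loc[(y, a)] + pop.loc[(y + 1, a)]) / 2.0
            for m in range(1, 13):
                rows.append((m, y, a, py_annual, py_annual * days_in_month(y, m) / nd_year))
    out = pd.DataFrame(rows, columns=["month", "year", "age", "py_annual", "py"])
    out.attrs["construction"] = "census"
    return out


def reference_rates(cases_by_age: pd.Series | pd.DataFrame,
                    py: pd.DataFrame, mode: str = "pooled") -> pd.Series | pd.DataFrame:
    """Age-specific reference incidence rates (cases per person-year).

    ``mode="pooled"`` divides the total cases at each age by the total
    person-years at that age over the whole period; ``mode="annual"`` does the
    same within each year (the table then needs ``year, age, observed``).
    """
    if mode == "pooled":
        s = cases_by_age if isinstance(cases_by_age, pd.Series) else \
            cases_by_age.groupby("age")["observed"].sum()
        py_a = py.groupby("age")["py"].sum().reindex(s.index, fill_value=0.0)
        bad = (py_a == 0) & (s > 0)
        if bad.any():
            raise ValueError(f"cases observed at ages with zero person-years: "
                             f"{list(s.index[bad])}")
        with np.errstate(invalid="ignore"):
            rates = (s / py_a).fillna(0.0)
        rates.name = "rate"
        return rates
    if mode == "annual":
        if isinstance(cases_by_age, pd.Series):
            raise ValueError("annual mode needs a year,age,observed table")
        obs = cases_by_age.set_index(["year", "age"])["observed"]
        py_ya = py.groupby(["year", "age"])["py"].sum().reindex(obs.index, fill_value=0.0)
        bad = (py_ya == 0) & (obs > 0)
        if bad.any():
            raise ValueError("cases observed in (year, age) cells with zero person-years")
        with np.errstate(invalid="ignore"):
            rates = (obs / py_ya).fillna(0.0)
        return rates.rename("rate").reset_index()
    raise ValueError(f"mode must be 'pooled' or 'annual', got {mode!r}")


def expected_counts(rates: pd.Series | pd.DataFrame, py: pd.DataFrame,
                    standardise: bool = True,
                    total_observed: float | None = None) -> pd.DataFrame:
    """Expected cases per (year, period): E_{m,y} = sum_a rate * PY_{m,y,a}.

    With ``standardise=True`` all cells are rescaled by a single constant so
    the expected total equals ``total_observed`` (internal standardisation);
    when the rates come from the same cohort the rescaling constant is 1 up to
    rounding. The period index is the person-years month.
    """
    tab = py.copy()
    if isinstance(rates, pd.Series):
        tab = tab.merge(rates.rename("rate").reset_index(), on="age", how="left")
    else:
        tab = tab.merge(rates, on=["year", "age"], how="left")
    if tab["rate"].isna().any():
        raise ValueError("reference rates do not cover every (year, age) in the person-years table")
    tab["expected"] = tab["rate"] * tab["py"]
    out = (tab.groupby(["year", "month"])["expected"].sum()
              .rename_axis(["year", "period"]).reset_index())
    total = out["expected"].sum()
    if total <= 0:
        raise ValueError("expected counts are all zero; rates or person-years are degenerate")
    if standardise:
        if total_observed is None:
            raise ValueError("standardise=True needs the cohort's observed total")
        out["expected"] *= total_observed / total
    return out
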