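"""End-to-end analysis orchestration.

``run_analysis`` composes the full chain for one cohort: filter cases, build
person-years on the requested axis, derive internally standardised expected
counts, then monthly SIRs, the heterogeneity LRT, the seasonal scan with
Monte-Carlo inference and, when per-year data are available, the year-to-year
reproducibility of the detected window. ``run_sensitivity_midmonth`` repeats
the chain on twelve 30-day periods cut at mid-month, the standard robustness
check for cluster borders that straddle calendar months.

Inputs are either case-level (cases + births and/or census) or a precomputed
12-row observed/expected series; the latter supports everything except the
per-year reproducibility table and the midmonth recoding (which need dates).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import exposure, registry, reproducibility, sir
from .scan import ScanResult, scan as run_scan
from .series import N_PERIODS, OESeries, collapse_to_loop

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class AnalysisReport:
    cohort: dict
    monthly: list[sir.SIREstimate]
    heterogeneity: sir.HeterogeneityResult
    scan: ScanResult
    reproducibility: reproducibility.SIRRResult | None
    provenance: dict

    @property
    def n_cases(self) -> int:
        return int(self.cohort["n"])

    def to_dict(self) -> dict:
        d = {
            "cohort": self.cohort,
            "monthly_sirs": [m.to_dict() for m in self.monthly],
            "heterogeneity": self.heterogeneity.to_dict(),
            "scan": self.scan.to_dict(),
            "provenance": self.provenance,
        }
        if self.reproducibility is not None:
            r = self.reproducibility
            d["reproducibility"] = {
                "per_year": r.per_year.replace([np.inf, -np.inf], None)
                              .where(pd.notna(r.per_year), None)
                              .to_dict(orient="records"),
                "overall": r.overall.to_dict(),
                "interaction_lr": r.interaction_lr, "df": r.df, "p": r.p_value,
            }
        else:
            d["reproducibility"] = None
        return d

    def to_json(self, path=None, indent: int = 2) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not JSON serialisable: {type(o)}")
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True,
                          default=_default, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


class EmptyCohortError(ValueError):
    """No cases remain after filtering; the report cannot be built."""


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _expected_for(cases: pd.DataFrame, spec: registry.CohortSpec,
                  births: pd.DataFrame | None, census: pd.DataFrame | None,
                  rate_mode: str = "pooled") -> pd.DataFrame:
    """Internally standardised expected counts per (year, period)."""
    if spec.axis == "birth":
        if births is None:
            raise ValueError("birth-axis analyses need monthly birth counts")
        py = exposure.birth_cohort_person_years(births, end_year=spec.study_years[1])
    else:
        if census is None:
            raise ValueError("diagnosis-axis analyses need census populations")
        py = exposure.census_person_years(census, spec.study_years)
    if rate_mode == "pooled":
        cases_by_age = registry.counts_by_age(cases, spec)
    else:
        cases_by_age = registry.counts_by_year_and_age(cases, spec)
    rates = exposure.reference_rates(cases_by_age, py, mode=rate_mode)
    n = int(registry.aggregate_counts(cases, spec, "calendar")["observed"].sum())
    return exposure.expected_counts(rates, py, standardise=True, total_observed=n)


def build_tables(cases: pd.DataFrame, spec: registry.CohortSpec,
                 births: pd.DataFrame | None = None,
                 census: pd.DataFrame | None = None,
                 rate_mode: str = "pooled") -> pd.DataFrame:
    """The (year, period, observed, expected) table for one cohort (calendar)."""
    obs = registry.aggregate_counts(cases, spec, "calendar")
    if obs["observed"].sum() == 0:
        raise EmptyCohortError(f"no cases in cohort ({spec.describe()})")
    exp = _expected_for(cases, spec, births, census, rate_mode)
    merged = obs.merge(exp, on=["year", "period"], how="left")
    merged["expected"] = merged["expected"].fillna(0.0)
    return merged


def _analyse_series(series: OESeries, table: pd.DataFrame | None, cohort: dict,
                    max_len: int, nsim: int, seed: int | None,
                    ci_method: str) -> AnalysisReport:
    monthly = sir.monthly_sirs(series, ci_method=ci_method)
    het = sir.heterogeneity_test(series)
    scan_res = run_scan(series, max_len=max_len, nsim=nsim, seed=seed,
                             ci_method=ci_method)
    repro = None
    if table is not None and table["year"].nunique() >= 2:
        repro = reproducibility.sirr_heterogeneity_test(table, scan_res.window)
    provenance = {
        "package": "seasonscan", "version": __version__,
        "nsim": nsim, "seed": seed, "max_window": max_len,
        "ci_method": ci_method,
        "config_hash": _config_hash({**cohort, "nsim": nsim, "seed": seed,
                                     "max_len": max_len, "ci_method": ci_method}),
        "caveat": ("exploratory analysis: groups and axes are analysed "
                   "independently with no multiplicity adjustment"),
    }
    return AnalysisReport(cohort, monthly, het, scan_res, repro, provenance)


def run_analysis(spec: registry.CohortSpec,
                 cases: pd.DataFrame | None = None,
                 births: pd.DataFrame | None = None,
                 census: pd.DataFrame | None = None,
                 oe: OESeries | None = None,
                 max_len: int = 6, nsim: int = 9999, seed: int | None = None,
                 rate_mode: str = "pooled",
                 ci_method: str = "profile") -> AnalysisReport:
    """Run the full seasonality analysis for one cohort.

    Provide either ``oe`` (a precomputed 12-row series) or ``cases`` together
    with ``births`` (birth axis) / ``census`` (diagnosis axis). Raises
    :class:`EmptyCohortError` when filtering leaves no cases.
    """
    if (oe is None) == (cases is None):
        raise ValueError("provide exactly one of `oe` or `cases`")
    table = None
    if oe is None:
        table = build_tables(cases, spec, births, census, rate_mode)
        if table["observed"].sum() == 0:
            raise EmptyCohortError(f"no cases in cohort ({spec.describe()})")
        series = collapse_to_loop(table)
    else:
        series = oe
    cohort = {
        "group": spec.group, "axis": spec.axis, "scheme": series.scheme,
        "filters": {k: getattr(spec, k) for k in
                    ("sex", "laterality", "stage", "mycn", "age_cutoff_months")},
        "study_years": list(spec.study_years),
        "n": series.total_observed,
    }
    log.info("analysis %s: n=%d cases over %d periods",
             spec.describe(), series.total_observed, N_PERIODS)
    return _analyse_series(series, table, cohort, max_len, nsim, seed, ci_method)


def midmonth_expected(expected: pd.DataFrame,
                      study_years: tuple[int, int]) -> pd.DataFrame:
    """Recode calendar-month expected counts onto mid-month periods.

    Period p of year y spans day 15 of month p through day 14 of month p+1;
    its expected count is the day-weighted split of the two calendar months:
    E_p = E_p^cal * (ND_p - 14)/ND_p + E_{p+1}^cal * 14/ND_{p+1}. December
    wraps into January of the following year; the final study year's period
    12 is truncated at the study end, so its January share is zero.
    """
    lo, hi = study_years
    e = expected.set_index(["year", "period"])["expected"]
    rows = []
    for y in range(lo, hi + 1):
        for p in range(1, N_PERIODS + 1):
            nd_p = exposure.days_in_month(y, p)
            share = e.loc[(y, p)] * (nd_p - 14) / nd_p
            if p < N_PERIODS:
                nd_q = exposure.days_in_month(y, p + 1)
                share += e.loc[(y, p + 1)] * 14 / nd_q
            elif y + 1 <= hi:
                nd_q = exposure.days_in_month(y + 1, 1)
                share += e.loc[(y + 1, 1)] * 14 / nd_q
            rows.append((y, p, share))
    return pd.DataFrame(rows, columns=["year", "period", "expected"])


def run_sensitivity_midmonth(spec: registry.CohortSpec,
                             cases: pd.DataFrame,
                             births: pd.DataFrame | None = None,
                             census: pd.DataFrame | None = None,
                             max_len: int = 6, nsim: int = 9999,
                             seed: int | None = None, rate_mode: str = "pooled",
                             ci_method: str = "profile") -> AnalysisReport:
    """The same pipeline on mid-month periods (needs case-level dates)."""
    if cases is None:
        raise ValueError("the midmonth sensitivity analysis needs case-level "
                         "input; a precomputed oe series cannot be recoded")
    obs = registry.aggregate_counts(cases, spec, "midmonth")
    if obs["observed"].sum() == 0:
        raise EmptyCohortError(f"no cases in cohort ({spec.describe()})")
    exp_cal = _expected_for(cases, spec, births, census, rate_mode)
    exp_mid = midmonth_expected(exp_cal, spec.study_years)
    table = obs.merge(exp_mid, on=["year", "period"], how="left")
    table["expected"] = table["expected"].fillna(0.0)
    # renormalise: truncation at the study edges shaves a few expected days
    total_obs = table["observed"].sum()
    if total_obs == 0:
        raise EmptyCohortError(f"no cases in cohort ({spec.describe()})")
    table["expected"] *= total_obs / table["expected"].sum()
    series = collapse_to_loop(table, scheme="midmonth")
    cohort = {
        "group": spec.group, "axis": spec.axis, "scheme": "midmonth",
        "filters": {k: getattr(spec, k) for k in
                    ("sex", "laterality", "stage", "mycn", "age_cutoff_months")},
        "study_years": list(spec.study_years),
        "n": series.total_observed,
    }
    return _analyse_series(series, table, cohort, max_len, nsim, seed, ci_method)
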