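"""Case-level registry records: reading, validation, filtering, binning.

A case table is a :class:`pandas.DataFrame` with one row per tumour case and
the columns ``case_id, group, sex, birth_date, diagnosis_date, laterality,
stage, mycn``. Dates are ISO-8601; attribute fields that do not apply to a
diagnostic group are empty (NA). Validation enforces the registry rules:
diagnosis on or after birth, diagnosis before the 15th birthday, laterality
recorded only for retinoblastoma, stage and MYCN status only for
neuroblastoma.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import N_PERIODS

log = logging.getLogger(__name__)

GROUPS = ("neuroblastoma", "nephroblastoma", "medulloblastoma",
          "rhabdomyosarcoma", "retinoblastoma", "hepatoblastoma")
SEXES = ("M", "F")
LATERALITIES = ("unilateral", "bilateral")
STAGES = ("localised", "metastatic")
MYCN_STATUSES = ("amplified", "not_amplified", "unknown")

CASE_COLUMNS = ["case_id", "group", "sex", "birth_date", "diagnosis_date",
                "laterality", "stage", "mycn"]

MAX_AGE_YEARS = 15  # follow-up stops the day before the 15th birthday


class CaseFormatError(ValueError):
    """The case file as a whole is malformed (missing columns etc.)."""


@dataclass(frozen=True)
class CohortSpec:
    """Which cases enter an analysis, and along which time axis.

    ``axis`` selects the date that is binned into periods: ``"birth"`` bins
    the birth date (cases born outside ``study_years`` are dropped),
    ``"diagnosis"`` bins the diagnosis date. ``age_cutoff_months`` with
    ``age_side`` restricts on age at diagnosis in completed months
    (``"le"`` keeps ages <= cutoff, ``"gt"`` ages > cutoff).
    """

    group: str | None = None
    sex: str | None = None
    laterality: str | None = None
    stage: str | None = None
    mycn: str | None = None
    age_cutoff_months: int | None = None
    age_side: str = "le"
    axis: str = "diagnosis"
    study_years: tuple[int, int] = (2000, 2015)

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown diagnostic group {self.group!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.laterality is not None and self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.stage is not None and self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.mycn is not None and self.mycn not in MYCN_STATUSES:
            raise ValueError(f"unknown MYCN status {self.mycn!r}")
        if self.axis not in ("birth", "diagnosis"):
            raise ValueError(f"axis must be 'birth' or 'diagnosis', got {self.axis!r}")
        if self.age_side not in ("le", "gt"):
            raise ValueError("age_side must be 'le' or 'gt'")
        lo, hi = self.study_years
        if hi < lo:
            raise ValueError("study_years range is empty")
        if self.age_cutoff_months is not None and self.group != "neuroblastoma":
            warnings.warn("age-at-diagnosis cutoffs are intended for the "
                          "neuroblastoma analyses", stacklevel=2)

    def describe(self) -> str:
        parts = [self.group or "all groups", f"axis={self.axis}"]
        for name in ("sex", "laterality", "stage", "mycn"):
            v = getattr(self, name)
            if v is not None:
                parts.append(f"{name}={v}")
        if self.age_cutoff_months is not None:
            op = "<=" if self.age_side == "le" else ">"
            parts.append(f"age{op}{self.age_cutoff_months}mo")
        return ", ".join(parts)


def age_at_diagnosis_months(birth_date: dt.date, diagnosis_date: dt.date) -> int:
    """Completed months between birth and diagnosis.

    Day-of-month aware: a month is not counted until the same day of month is
    reached (the 29th/30th/31st map onto shorter months' last day).
    """
    if diagnosis_date < birth_date:
        raise ValueError("diagnosis_date precedes birth_date")
    months = (diagnosis_date.year - birth_date.year) * 12 + (diagnosis_date.month - birth_date.month)
    if diagnosis_date.day < birth_date.day:
        # unless birth fell beyond the end of the diagnosis month
        last_day = _days_in_month(diagnosis_date.year, diagnosis_date.month)
        if not (birth_date.day > last_day and diagnosis_date.day == last_day):
            months -= 1
    return months


def age_at_diagnosis_years(birth_date: dt.date, diagnosis_date: dt.date) -> int:
    """Completed years at diagnosis."""
    return age_at_diagnosis_months(birth_date, diagnosis_date) // 12


def _days_in_month(year: int, month: int) -> int:
    import calendar
    return calendar.monthrange(year, month)[1]


def assign_period(date: dt.date, scheme: str = "calendar") -> tuple[int, int]:
    """Map a date to a (period, period_year) pair under the chosen scheme.

    Calendar scheme: period = calendar month, year = calendar year. Midmonth
    scheme: period p runs from the 15th of month p to the 14th of month p+1;
    period 12 wraps 15 December of year y to 14 January of year y+1 and is
    attributed to year y.
    """
    if scheme == "calendar":
        return date.month, date.year
    if scheme == "midmonth":
        if date.day >= 15:
            return date.month, date.year
        period = date.month - 1
        if period == 0:
            return 12, date.year - 1
        return period, date.year
    raise ValueError(f"unknown scheme {scheme!r}")


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    errors: list[str] = []
    keep = np.ones(len(df), dtype=bool)

    def reject(mask: np.ndarray, rule: str) -> None:
        for idx in df.index[mask & keep]:
            errors.append(f"row {idx + 2}: {rule}")  # +2: header line + 1-basing
        keep[np.asarray(mask)] = False

    reject(~df["group"].isin(GROUPS).to_numpy(), "unknown diagnostic group")
    reject(~df["sex"].isin(SEXES).to_numpy(), "unknown sex")

    bdate = pd.to_datetime(df["birth_date"], format="%Y-%m-%d", errors="coerce")
    ddate = pd.to_datetime(df["diagnosis_date"], format="%Y-%m-%d", errors="coerce")
    reject(bdate.isna().to_numpy(), "unparseable birth_date")
    reject(ddate.isna().to_numpy(), "unparseable diagnosis_date")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NaT comparisons
        reject((ddate < bdate).to_numpy(), "diagnosis_date precedes birth_date")
    age_ok = np.zeros(len(df), dtype=bool)
    for i, (b, d) in enumerate(zip(bdate, ddate)):
        if pd.isna(b) or pd.isna(d) or d < b:
            continue
        age_ok[i] = age_at_diagnosis_months(b.date(), d.date()) < 12 * MAX_AGE_YEARS
    reject(~age_ok & keep, "age at diagnosis is 15 years or more")

    lat = df["laterality"].fillna("")
    reject((~lat.isin(("",) + LATERALITIES)).to_numpy(), "unknown laterality")
    reject(((lat != "") & (df["group"] != "retinoblastoma")).to_numpy(),
           "laterality recorded for a non-retinoblastoma case")
    stage = df["stage"].fillna("")
    reject((~stage.isin(("",) + STAGES)).to_numpy(), "unknown stage")
    reject(((stage != "") & (df["group"] != "neuroblastoma")).to_numpy(),
           "stage recorded for a non-neuroblastoma case")
    mycn = df["mycn"].fillna("")
    reject((~mycn.isin(("",) + MYCN_STATUSES)).to_numpy(), "unknown MYCN status")
    reject(((mycn != "") & (df["group"] != "neuroblastoma")).to_numpy(),
           "MYCN status recorded for a non-neuroblastoma case")

    out = df.loc[keep].copy()
    out["birth_date"] = bdate[keep].dt.date
    out["diagnosis_date"] = ddate[keep].dt.date
    for col in ("laterality", "stage", "mycn"):
        out[col] = out[col].where(out[col].notna() & (out[col] != ""), None)
    return out.reset_index(drop=True), errors


def read_cases(path, on_invalid: str = "warn") -> pd.DataFrame:
    """Read and validate a case CSV.

    Rows violating registry invariants are dropped; ``on_invalid`` controls
    whether that raises (``"error"``), warns (``"warn"``) or is silent
    (``"ignore"``). Returns the validated case table.
    """
    df = pd.read_csv(path, dtype=str)
    missing = set(CASE_COLUMNS) - set(df.columns)
    if missing:
        raise CaseFormatError(f"case file is missing columns: {sorted(missing)}")
    df = df.loc[:, CASE_COLUMNS]
    valid, errors = _validate_rows(df)
    if errors:
        msg = f"{len(errors)} invalid case rows dropped: " + "; ".join(errors[:10])
        if on_invalid == "error":
            raise ValueError(msg)
        if on_invalid == "warn":
            warnings.warn(msg, stacklevel=2)
    return valid


def write_cases(cases: pd.DataFrame, path) -> None:
    """Write a case table back to the documented CSV layout (NA as empty)."""
    out = cases.loc[:, CASE_COLUMNS].copy()
    for col in ("birth_date", "diagnosis_date"):
        out[col] = out[col].map(lambda d: d.isoformat())
    out.to_csv(path, index=False, na_rep="")


def filter_cases(cases: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Apply the cohort filters (group, attributes, age cutoff, birth-axis span)."""
    m = np.ones(len(cases), dtype=bool)
    if spec.group is not None:
        m &= (cases["group"] == spec.group).to_numpy()
    if spec.sex is not None:
        m &= (cases["sex"] == spec.sex).to_numpy()
    if spec.laterality is not None:
        m &= (cases["laterality"] == spec.laterality).to_numpy()
    if spec.stage is not None:
        m &= (cases["stage"] == spec.stage).to_numpy()
    if spec.mycn is not None:
        m &= (cases["mycn"] == spec.mycn).to_numpy()
    out = cases.loc[m]
    if spec.age_cutoff_months is not None:
        ages = out.apply(lambda r: age_at_diagnosis_months(r["birth_date"], r["diagnosis_date"]),
                         axis=1)
        if spec.age_side == "le":
            out = out.loc[(ages <= spec.age_cutoff_months).to_numpy(bool)]
        else:
            out = out.loc[(ages > spec.age_cutoff_months).to_numpy(bool)]
    if spec.axis == "birth":
        lo, hi = spec.study_years
        years = out["birth_date"].map(lambda d: d.year)
        out = out.loc[((years >= lo) & (years <= hi)).to_numpy(bool)]
    return out.reset_index(drop=True)


def aggregate_counts(cases: pd.DataFrame, spec: CohortSpec,
                     scheme: str = "calendar") -> pd.DataFrame:
    """Bin filtered cases into (year, period) observed counts.

    Returns a complete ``year, period, observed`` grid over the study years;
    the binned date is the one named by ``spec.axis``. Under the midmonth
    scheme the first study year's 1-14 January dates belong to the wrap-around
    December-January period; on the circular loop they have a period but no
    preceding study year, so they are clamped to the first year (totals are
    conserved; the per-year table is approximate only at that one edge).
    """
    kept = filter_cases(cases, spec)
    if len(kept) == 0:
        warnings.warn(f"no cases left after filtering ({spec.describe()})", stacklevel=2)
    datecol = "birth_date" if spec.axis == "birth" else "diagnosis_date"
    lo, hi = spec.study_years

    grid = pd.MultiIndex.from_product(
        [range(lo, hi + 1), range(1, N_PERIODS + 1)], names=["year", "period"])
    counts = pd.Series(0, index=grid, dtype=np.int64)
    clamped = 0
    dropped = 0
    for d in kept[datecol]:
        period, pyear = assign_period(d, scheme)
        if pyear < lo and lo <= d.year <= hi:
            pyear = lo
            clamped += 1
        if not lo <= pyear <= hi:
            dropped += 1
            continue
        counts.loc[(pyear, period)] += 1
    if dropped:
        warnings.warn(f"{dropped} case(s) dated outside the study years were "
                      "not binned", stacklevel=2)
    if clamped:
        warnings.warn(f"{clamped} case(s) on the start-of-study wrap-around edge "
                      f"were attributed to {lo} period 12", stacklevel=2)
    out = counts.rename("observed").reset_index()
    out.attrs["scheme"] = scheme
    out.attrs["axis"] = spec.axis
    return out


def counts_by_age(cases: pd.DataFrame, spec: CohortSpec) -> pd.Series:
    """Observed case counts by completed age (0..14) at diagnosis.

    For the birth axis, age is still age at diagnosis; this feeds the
    age-specific reference rates.
    """
    kept = filter_cases(cases, spec)
    ages = [age_at_diagnosis_years(b, d)
            for b, d in zip(kept["birth_date"], kept["diagnosis_date"])]
    s = pd.Series(ages, dtype=np.int64).value_counts().reindex(range(MAX_AGE_YEARS), fill_value=0)
    s.index.name = "age"
    return s.sort_index()


def counts_by_year_and_age(cases: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Observed counts by (reference year, age): birth year for the birth axis,
    diagnosis year otherwise."""
    kept = filter_cases(cases, spec)
    datecol = "birth_date" if spec.axis == "birth" else "diagnosis_date"
    years = kept[datecol].map(lambda d: d.year)
    ages = [age_at_diagnosis_years(b, d)
            for b, d in zip(kept["birth_date"], kept["diagnosis_date"])]
    df = pd.DataFrame({"year": years.to_numpy(), "age": ages})
    lo, hi = spec.study_years
    grid = pd.MultiIndex.from_product([range(lo, hi + 1), range(MAX_AGE_YEARS)],
                                      names=["year", "age"])
    out = df.value_counts().reindex(grid, fill_value=0).rename("observed").reset_index()
    return out
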