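"""Synthetic registry generator with known ground truth.

Emulates a national childhood cancer registry feeding the analysis pipeline:
a stable birth series (about 65,000 live births per month), a stable census
population (about 11 million children under 15), an age-specific incidence
profile scaled to a chosen annual group rate (default 12.3 cases per million
children per year, a neuroblastoma-like group), and an optional injected
multiplicative seasonal effect — a rate ratio rho applied to the birth-month
or diagnosis-month rate inside a chosen window.

Counts are drawn Poisson at the (period, year, age) cell level with mean
rate_a * PY_{m,y,a} * rho^[m in window], then materialised as individual case
records with dates uniform within their cell and attributes drawn from the
configured mixtures. Drawing at cell level guarantees the exact Poisson
structure the inferential code assumes. One seed drives a single documented
stream order (cell counts, then attributes, then dates), so a configuration
plus a seed reproduces the registry byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exposure, registry
from .scan import Window

#: age weights of the default incidence profile: share of cases by completed
#: age, front-loaded like embryonal tumours (about 40% in the first year of
#: life, 80% before age five)
DEFAULT_AGE_WEIGHTS = np.array(
    [0.390, 0.176, 0.143, 0.077, 0.077] + [0.0137] * 10)
DEFAULT_AGE_WEIGHTS = DEFAULT_AGE_WEIGHTS / DEFAULT_AGE_WEIGHTS.sum()

#: default attribute mixtures per diagnostic group (sex ratios and the
#: neuroblastoma/retinoblastoma-specific strata of a large national registry)
DEFAULT_ATTRIBUTES: dict[str, dict] = {
    "neuroblastoma": {"p_male": 0.529, "p_metastatic": 0.474,
                      "p_mycn": {"not_amplified": 0.685, "amplified": 0.167,
                                 "unknown": 0.148}},
    "nephroblastoma": {"p_male": 0.468},
    "medulloblastoma": {"p_male": 0.643},
    "rhabdomyosarcoma": {"p_male": 0.620},
    "retinoblastoma": {"p_male": 0.505, "p_unilateral": 0.692},
    "hepatoblastoma": {"p_male": 0.614},
}


@dataclass(frozen=True)
class SeasonalEffect:
    """Multiplicative rate ratio ``rho`` on a window of periods along one axis."""

    axis: str = "birth"  # which month the effect multiplies
    window: Window = field(default_factory=lambda: Window(6, 3))
    rate_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.axis not in ("birth", "diagnosis"):
            raise ValueError("seasonal effect axis must be 'birth' or 'diagnosis'")
        if self.rate_ratio < 0:
            raise ValueError("rate_ratio must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    study_years: tuple[int, int] = (2000, 2015)
    births_per_month: float = 65_000.0
    population_per_age: float = 733_000.0  # ~11 million children aged 0-14
    group: str = "neuroblastoma"
    annual_rate_per_million: float = 12.3
    age_weights: tuple = tuple(DEFAULT_AGE_WEIGHTS)
    effect: SeasonalEffect = field(default_factory=SeasonalEffect)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in registry.GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        w = np.asarray(self.age_weights, float)
        if len(w) != exposure.MAX_AGE + 1 or np.any(w < 0):
            raise ValueError("age_weights must be 15 non-negative values")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("age_weights must sum to 1")
        if self.annual_rate_per_million < 0 or self.births_per_month < 0 \
                or self.population_per_age < 0:
            raise ValueError("rates and population sizes must be non-negative")

    @property
    def age_rates(self) -> np.ndarray:
        """Cases per person-year at each completed age 0..14.

        Scaled so that the population-average annual rate equals
        ``annual_rate_per_million`` when every age has the same population.
        """
        w = np.asarray(self.age_weights, float)
        return self.annual_rate_per_million * 1e-6 * (exposure.MAX_AGE + 1) * w

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect"] = {"axis": self.effect.axis,
                       "window_start": self.effect.window.start,
                       "window_length": self.effect.window.length,
                       "rate_ratio": self.effect.rate_ratio}
        d["age_weights"] = [float(x) for x in self.age_weights]
        d["study_years"] = list(self.study_years)
        return d


def generate_births(config: SyntheticConfig) -> pd.DataFrame:
    """Monthly live-birth counts: a constant grid (deterministic)."""
    lo, hi = config.study_years
    years = np.repeat(np.arange(lo, hi + 1), 12)
    months = np.tile(np.arange(1, 13), hi - lo + 1)
    return pd.DataFrame({"year": years, "month": months,
                         "n_births": config.births_per_month})


def generate_census(config: SyntheticConfig) -> pd.DataFrame:
    """1-January populations by year and age, one year past the study end."""
    lo, hi = config.study_years
    years = np.repeat(np.arange(lo, hi + 2), exposure.MAX_AGE + 1)
    ages = np.tile(np.arange(exposure.MAX_AGE + 1), hi - lo + 2)
    return pd.DataFrame({"year": years, "age": ages,
                         "population": config.population_per_age})


def _cell_lambdas(config: SyntheticConfig) -> pd.DataFrame:
    """Poisson means per (month, year, age) cell, seasonal effect applied."""
    axis = config.effect.axis
    if axis == "birth":
        py = exposure.birth_cohort_person_years(generate_births(config),
                                                end_year=config.study_years[1])
    else:
        py = exposure.census_person_years(generate_census(config), config.study_years)
    rates = config.age_rates
    lam = py.copy()
    lam["lam"] = lam["py"] * rates[lam["age"].to_numpy()]
    members = set(config.effect.window.members())
    in_window = lam["month"].isin(members)
    lam.loc[in_window, "lam"] *= config.effect.rate_ratio
    return lam.loc[lam["lam"] > 0, ["month", "year", "age", "lam"]].reset_index(drop=True)


def _uniform_day_in_month(rng: np.random.Generator, year: int, month: int) -> dt.date:
    day = int(rng.integers(1, exposure.days_in_month(year, month) + 1))
    return dt.date(year, month, day)


def generate_cases(config: SyntheticConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a full synthetic case table under the configured model.

    For the birth axis, a cell (m, y, a) is the cohort born in month m of
    year y and diagnosed at completed age a; the diagnosis date is uniform on
    the at-risk part of that age-year (truncated at the study end). For the
    diagnosis axis, the cell is diagnoses in month m of year y at completed
    age a, and the birth date is back-calculated to be consistent with a.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam = _cell_lambdas(config)
    counts = rng.poisson(lam["lam"].to_numpy())
    cells = lam.loc[np.repeat(lam.index, counts)].reset_index(drop=True)
    n = len(cells)
    attrs = _draw_attributes(config, n, rng)
    study_end = dt.date(config.study_years[1], 12, 31)

    birth_dates: list[dt.date] = []
    diagnosis_dates: list[dt.date] = []
    if config.effect.axis == "birth":
        for m, y, a in zip(cells["month"], cells["year"], cells["age"]):
            b = _uniform_day_in_month(rng, int(y), int(m))
            lo_d = _add_years(b, int(a))
            hi_d = min(_add_years(b, int(a) + 1) - dt.timedelta(days=1), study_end)
            span = (hi_d - lo_d).days
            d = lo_d + dt.timedelta(days=int(rng.integers(0, span + 1)))
            birth_dates.append(b)
            diagnosis_dates.append(d)
    else:
        for m, y, a in zip(cells["month"], cells["year"], cells["age"]):
            d = _uniform_day_in_month(rng, int(y), int(m))
            b = _add_years(d, -int(a)) - dt.timedelta(days=int(rng.integers(0, 365)))
            birth_dates.append(b)
            diagnosis_dates.append(d)

    out = pd.DataFrame({
        "case_id": [f"S{i:06d}" for i in range(1, n + 1)],
        "group": config.group,
        "sex": attrs["sex"],
        "birth_date": birth_dates,
        "diagnosis_date": diagnosis_dates,
        "laterality": attrs["laterality"],
        "stage": attrs["stage"],
        "mycn": attrs["mycn"],
    })
    return out


def _add_years(d: dt.date, years: int) -> dt.date:
    """Calendar-year shift clamping 29 February onto 28 February."""
    try:
        return d.replace(year=d.year + years)
    except ValueError:
        return d.replace(year=d.year + years, day=28)


def _draw_attributes(config: SyntheticConfig, n: int,
                     rng: np.random.Generator) -> dict[str, list]:
    mix = DEFAULT_ATTRIBUTES[config.group]
    sex = np.where(rng.random(n) < mix["p_male"], "M", "F").tolist()
    laterality: list = [None] * n
    stage: list = [None] * n
    mycn: list = [None] * n
    if config.group == "retinoblastoma":
        laterality = np.where(rng.random(n) < mix["p_unilateral"],
                              "unilateral", "bilateral").tolist()
    if config.group == "neuroblastoma":
        stage = np.where(rng.random(n) < mix["p_metastatic"],
                         "metastatic", "localised").tolist()
        keys = list(mix["p_mycn"])
        probs = np.array([mix["p_mycn"][k] for k in keys])
        mycn = [keys[i] for i in rng.choice(len(keys), size=n, p=probs / probs.sum())]
    return {"sex": sex, "laterality": laterality, "stage": stage, "mycn": mycn}


def write_registry(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Materialise cases.csv, births.csv, census.csv and the resolved config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cases": outdir / "cases.csv",
        "births": outdir / "births.csv",
        "census": outdir / "census.csv",
        "config": outdir / "config.yaml",
    }
    registry.write_cases(generate_cases(config), paths["cases"])
    generate_births(config).to_csv(paths["births"], index=False)
    generate_census(config).to_csv(paths["census"], index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return paths


def null_and_alt_fixtures(seed: int, rate_ratio: float = 1.5,
                          window: Window | None = None, axis: str = "birth",
                          **config_kwargs) -> tuple[pd.DataFrame, pd.DataFrame,
                                                    SyntheticConfig, SyntheticConfig]:
    """A matched (null, alternative) pair of case tables sharing a seed.

    The null member has rate ratio 1, the alternative injects ``rate_ratio``
    on ``window`` (default June-August); both are drawn from the same seed so
    power comparisons are paired.
    """
    window = window or Window(6, 3)
    null_cfg = SyntheticConfig(
        effect=SeasonalEffect(axis=axis, window=window, rate_ratio=1.0),
        seed=seed, **config_kwargs)
    alt_cfg = SyntheticConfig(
        effect=SeasonalEffect(axis=axis, window=window, rate_ratio=rate_ratio),
        seed=seed, **config_kwargs)
    return (generate_cases(null_cfg), generate_cases(alt_cfg), null_cfg, alt_cfg)
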