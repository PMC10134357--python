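"""Circular monthly observed/expected series.

The sufficient statistic for every test in this package is a set of twelve
(observed, expected) pairs laid out on the circular year (December adjoins
January). :class:`OESeries` holds the year-aggregated loop; the per-year
(year, period) table is kept as a plain :class:`pandas.DataFrame` with columns
``year, period, observed, expected`` so that the reproducibility analysis can
work year by year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
              "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]

N_PERIODS = 12


@dataclass(frozen=True)
class OESeries:
    """Twelve circular (observed, expected) monthly pairs.

    Parameters
    ----------
    observed
        Non-negative integer case counts, period 1..12.
    expected
        Positive real expected counts on the same periods.
    scheme
        ``"calendar"`` for calendar months, ``"midmonth"`` for 30-day periods
        running from the 15th of one month to the 14th of the next.
    """

    observed: np.ndarray
    expected: np.ndarray
    scheme: str = "calendar"

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        exp = np.asarray(self.expected, dtype=float)
        if obs.shape != (N_PERIODS,) or exp.shape != (N_PERIODS,):
            raise ValueError("an OESeries needs exactly 12 observed and 12 expected values")
        if np.any(obs < 0) or np.any(~np.isfinite(obs)):
            raise ValueError("observed counts must be finite and non-negative")
        if np.any(exp < 0) or np.any(~np.isfinite(exp)):
            raise ValueError("expected counts must be finite and non-negative")
        if not np.allclose(obs, np.round(obs)):
            raise ValueError("observed counts must be integers")
        object.__setattr__(self, "observed", np.round(obs).astype(np.int64))
        object.__setattr__(self, "expected", exp)
        if self.scheme not in ("calendar", "midmonth"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def total_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def total_expected(self) -> float:
        return float(self.expected.sum())

    def period_label(self, period: int) -> str:
        """Human-readable label of a period (1..12)."""
        if not 1 <= period <= N_PERIODS:
            raise ValueError(f"period must be 1..12, got {period}")
        if self.scheme == "calendar":
            return MONTH_ABBR[period - 1]
        nxt = period % N_PERIODS
        return f"15 {MONTH_ABBR[period - 1]}-14 {MONTH_ABBR[nxt]}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"period": np.arange(1, N_PERIODS + 1),
             "observed": self.observed,
             "expected": self.expected}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scheme: str = "calendar") -> "OESeries":
        """Read a ``period,observed,expected`` CSV (the direct entry point)."""
        df = pd.read_csv(path)
        missing = {"period", "observed", "expected"} - set(df.columns)
        if missing:
            raise ValueError(f"oe csv is missing columns: {sorted(missing)}")
        df = df.sort_values("period")
        if list(df["period"]) != list(range(1, N_PERIODS + 1)):
            raise ValueError("oe csv must contain periods 1..12 exactly once each")
        return cls(df["observed"].to_numpy(), df["expected"].to_numpy(), scheme=scheme)


def validate_year_period_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a ``year, period, observed, expected`` table."""
    required = {"year", "period", "observed", "expected"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"year-period table is missing columns: {sorted(missing)}")
    out = table.loc[:, ["year", "period", "observed", "expected"]].copy()
    if out.duplicated(["year", "period"]).any():
        raise ValueError("duplicate (year, period) cells in table")
    if not out["period"].between(1, N_PERIODS).all():
        raise ValueError("periods must lie in 1..12")
    if (out["observed"] < 0).any() or (out["expected"] < 0).any():
        raise ValueError("counts must be non-negative")
    return out.sort_values(["year", "period"]).reset_index(drop=True)


def collapse_to_loop(table: pd.DataFrame, scheme: str = "calendar") -> OESeries:
    """Aggregate a (year, period) O/E table onto the 12-period circular loop.

    ``O_m = sum_y O_{m,y}`` and likewise for E; total counts are conserved.
    """
    table = validate_year_period_table(table)
    g = table.groupby("period")[["observed", "expected"]].sum()
    g = g.reindex(range(1, N_PERIODS + 1), fill_value=0.0)
    return OESeries(g["observed"].to_numpy(), g["expected"].to_numpy(), scheme=scheme)


def loop_from_counts(observed: pd.DataFrame, expected: pd.DataFrame,
                     scheme: str = "calendar") -> OESeries:
    """Join separate observed and expected (year, period) tables and collapse."""
    o = observed.rename(columns={observed.columns[-1]: "observed"})
    e = expected.rename(columns={expected.columns[-1]: "expected"})
    merged = o.merge(e, on=["year", "period"], how="outer")
    if merged[["observed", "expected"]].isna().any().any():
        raise ValueError("observed and expected tables are not on the same (year, period) grid")
    return collapse_to_loop(merged, scheme=scheme)
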