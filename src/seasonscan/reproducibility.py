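"""Year-to-year reproducibility of a detected seasonal cluster.

A seasonal pattern worth the name should recur: for a fixed cluster window,
the ratio of the inside SIR to the outside SIR (the SIRR) is computed for the
whole period and for each year separately, and between-year heterogeneity of
the SIRR is tested by a likelihood-ratio test for a year-by-window
interaction in the offset Poisson model.

The interaction test works on the Y x 2 table of (in-window, out-of-window)
counts per year. The null model has free year effects plus one shared window
effect; the alternative is saturated on the table. The null MLE is obtained
by profiling out the year effects, which reduces the fit to a monotone
one-dimensional score equation in the window effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta, chi2

from .series import OESeries, validate_year_period_table
from .scan import Window


@dataclass(frozen=True)
class SIRREstimate:
    o_in: int
    e_in: float
    o_out: int
    e_out: float
    sirr: float  # inf when o_out == 0 (flagged undefined upper bound)
    ci_low: float
    ci_high: float  # nan when undefined
    label: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.sirr)

    def to_dict(self) -> dict:
        return {"label": self.label, "o_in": self.o_in, "e_in": self.e_in,
                "o_out": self.o_out, "e_out": self.e_out, "sirr": self.sirr,
                "ci_low": self.ci_low, "ci_high": self.ci_high}


@dataclass(frozen=True)
class SIRRResult:
    per_year: pd.DataFrame  # year, o_in, e_in, o_out, e_out, sirr, ci_low, ci_high
    overall: SIRREstimate
    interaction_lr: float
    df: int
    p_value: float


def _clopper_pearson(k: int, n: int, alpha: float) -> tuple[float, float]:
    lo = 0.0 if k == 0 else beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else beta.ppf(1 - alpha / 2, k + 1, n - k)
    return lo, hi


def sirr(o_in: int, e_in: float, o_out: int, e_out: float,
         alpha: float = 0.05, label: str = "") -> SIRREstimate:
    """SIRR = (O_in/E_in) / (O_out/E_out) with an exact conditional CI.

    Conditionally on N = O_in + O_out, O_in is Binomial(N, pi) with
    pi = sirr*E_in / (sirr*E_in + E_out); a Clopper-Pearson interval for pi is
    inverted to bounds on the sirr. With O_out = 0 the ratio is infinite and
    the upper bound undefined (returned as inf with ci_high = nan).
    """
    if e_in <= 0 or e_out <= 0:
        raise ValueError("expected counts must be positive on both sides of the window")
    if o_in < 0 or o_out < 0:
        raise ValueError("observed counts must be non-negative")
    n = o_in + o_out
    if n == 0:
        return SIRREstimate(0, e_in, 0, e_out, np.nan, np.nan, np.nan, label)
    ratio = e_out / e_in

    def pi_to_sirr(pi: float) -> float:
        if pi >= 1.0:
            return np.inf
        return pi / (1 - pi) * ratio

    pi_lo, pi_hi = _clopper_pearson(o_in, n, alpha)
    if o_out == 0:
        return SIRREstimate(o_in, e_in, 0, e_out, np.inf,
                            pi_to_sirr(pi_lo), np.nan, label)
    point = (o_in / e_in) / (o_out / e_out)
    return SIRREstimate(o_in, e_in, o_out, e_out, point,
                        pi_to_sirr(pi_lo), pi_to_sirr(pi_hi), label)


def _split_by_window(table: pd.DataFrame, window: Window) -> pd.DataFrame:
    """Aggregate a (year, period) O/E table into per-year in/out totals."""
    table = validate_year_period_table(table)
    members = set(window.members())
    if len(members) >= 12:
        raise ValueError("window must not cover the whole loop")
    inside = table["period"].isin(members)
    g_in = table.loc[inside].groupby("year")[["observed", "expected"]].sum()
    g_out = table.loc[~inside].groupby("year")[["observed", "expected"]].sum()
    out = g_in.join(g_out, lsuffix="_in", rsuffix="_out").fillna(0.0)
    out.columns = ["o_in", "e_in", "o_out", "e_out"]
    if (out["e_in"] <= 0).any() or (out["e_out"] <= 0).any():
        raise ValueError("every year needs positive expected counts inside and "
                         "outside the window")
    return out.reset_index()


def yearly_sirr_table(table: pd.DataFrame, window: Window,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-year SIRR records for a fixed window.

    Years with no cases at all are kept, flagged by ``sirr`` = NaN; years with
    cases only inside the window get an infinite sirr and an undefined upper
    bound (mirroring the dash such tables print).
    """
    split = _split_by_window(table, window)
    recs = []
    for row in split.itertuples(index=False):
        est = sirr(int(row.o_in), row.e_in, int(row.o_out), row.e_out,
                   alpha=alpha, label=str(row.year))
        recs.append({"year": row.year, "o_in": est.o_in, "e_in": est.e_in,
                     "o_out": est.o_out, "e_out": est.e_out, "sirr": est.sirr,
                     "ci_low": est.ci_low, "ci_high": est.ci_high})
    return pd.DataFrame(recs)


def _fit_shared_window_effect(split: pd.DataFrame) -> tuple[float, np.ndarray]:
    """Profile MLE of the shared window effect theta in the null model.

    Model: mu_{y,in} = E_{y,in} e^{a_y + theta}, mu_{y,out} = E_{y,out} e^{a_y}.
    Profiling a_y at fixed theta gives e^{a_y} = N_y / (E_in e^t + E_out); the
    remaining score equation in theta is monotone and bracketed by bisection.
    Returns (theta_hat, fitted means flattened as [in..., out...]).
    """
    o_in = split["o_in"].to_numpy(float)
    o_out = split["o_out"].to_numpy(float)
    e_in = split["e_in"].to_numpy(float)
    e_out = split["e_out"].to_numpy(float)
    n_y = o_in + o_out
    total_in = o_in.sum()

    def score(theta: float) -> float:
        t = np.exp(theta)
        return float(np.sum(n_y * e_in * t / (e_in * t + e_out)) - total_in)

    if total_in == 0:
        theta = -np.inf
        mu_in = np.zeros_like(e_in)
        mu_out = n_y.copy()
    elif o_out.sum() == 0:
        theta = np.inf
        mu_in = n_y.copy()
        mu_out = np.zeros_like(e_out)
    else:
        lo, hi = -1.0, 1.0
        while score(lo) > 0:
            lo *= 2
        while score(hi) < 0:
            hi *= 2
        theta = brentq(score, lo, hi, xtol=1e-12)
        t = np.exp(theta)
        a = n_y / (e_in * t + e_out)
        mu_in = a * e_in * t
        mu_out = a * e_out
    return theta, np.concatenate([mu_in, mu_out])


def sirr_heterogeneity_test(table: pd.DataFrame, window: Window) -> SIRRResult:
    """Between-year interaction LRT for the window effect, plus SIRR tables.

    The LR compares the shared-window-effect model against the model with a
    separate window effect per year (saturated on the Y x 2 table);
    df = Y - 1. The statistic is invariant to a global rescaling of E.
    """
    split = _split_by_window(table, window)
    n_years = len(split)
    if n_years < 2:
        raise ValueError("the interaction test needs at least two years")
    _, mu = _fit_shared_window_effect(split)
    obs = np.concatenate([split["o_in"].to_numpy(float), split["o_out"].to_numpy(float)])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = obs * np.log(obs / mu)
    lr = float(2.0 * np.nansum(np.where(obs > 0, terms, 0.0)))
    lr = max(lr, 0.0)
    df = n_years - 1
    p = float(chi2.sf(lr, df))
    overall = sirr(int(split["o_in"].sum()), float(split["e_in"].sum()),
                   int(split["o_out"].sum()), float(split["e_out"].sum()),
                   label="all years")
    return SIRRResult(yearly_sirr_table(table, window), overall, lr, df, p)
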