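"""Standardised incidence ratios and the monthly heterogeneity test.

The SIR for a month (or a window of months) is O/E, the observed over the
expected count. O is treated as a Poisson count with mean SIR * E, which is
the saturated-month Poisson regression with log E as offset: the closed-form
MLE of each month effect is exactly log(O_m/E_m), so no iterative fit is
needed.

Confidence intervals
--------------------
``profile`` (default) inverts the likelihood-ratio statistic for a Poisson
mean — the interval a Poisson GLM profile gives. ``garwood`` is the exact
(Garwood) interval from chi-square quantiles, which is conservative; both are
exposed because published registry tables use either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from .series import N_PERIODS, OESeries

CI_METHODS = ("profile", "garwood")


@dataclass(frozen=True)
class SIREstimate:
    observed: int
    expected: float
    sir: float
    ci_low: float
    ci_high: float
    label: str = ""
    alpha: float = 0.05
    ci_method: str = "profile"

    def to_dict(self) -> dict:
        return {"label": self.label, "observed": self.observed,
                "expected": self.expected, "sir": self.sir,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "ci_method": self.ci_method}


@dataclass(frozen=True)
class HeterogeneityResult:
    lr_stat: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"lr": self.lr_stat, "df": self.df, "p": self.p_value}


def _garwood_mean_ci(o: int, alpha: float) -> tuple[float, float]:
    lo = 0.0 if o == 0 else chi2.ppf(alpha / 2, 2 * o) / 2
    hi = chi2.ppf(1 - alpha / 2, 2 * (o + 1)) / 2
    return lo, hi


def _profile_mean_ci(o: int, alpha: float) -> tuple[float, float]:
    """Likelihood-ratio interval for a Poisson mean given a count ``o``."""
    q = chi2.ppf(1 - alpha, 1)
    if o == 0:
        return 0.0, q / 2  # deviance 2*mu = q
    def dev(mu: float) -> float:
        return 2.0 * (mu - o + o * np.log(o / mu))
    lo = brentq(lambda mu: dev(mu) - q, 1e-12, o)
    hi = brentq(lambda mu: dev(mu) - q, o, 10.0 * o + 100.0)
    return lo, hi


def sir_estimate(observed: int, expected: float, alpha: float = 0.05,
                 label: str = "", ci_method: str = "profile") -> SIREstimate:
    """Point SIR = O/E with a 95% (by default) confidence interval."""
    if expected <= 0:
        raise ValueError(f"expected count must be positive, got {expected}")
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if ci_method not in CI_METHODS:
        raise ValueError(f"ci_method must be one of {CI_METHODS}")
    o = int(observed)
    f = _profile_mean_ci if ci_method == "profile" else _garwood_mean_ci
    lo, hi = f(o, alpha)
    return SIREstimate(o, float(expected), o / expected, lo / expected, hi / expected,
                       label=label, alpha=alpha, ci_method=ci_method)


def monthly_sirs(series: OESeries, alpha: float = 0.05,
                 ci_method: str = "profile") -> list[SIREstimate]:
    """One SIR per period of the circular series (equal to exp of the
    saturated offset-model month effects)."""
    if np.any(series.expected <= 0):
        raise ValueError("every monthly expected count must be positive")
    return [sir_estimate(int(o), float(e), alpha=alpha,
                         label=series.period_label(m + 1), ci_method=ci_method)
            for m, (o, e) in enumerate(zip(series.observed, series.expected))]


def heterogeneity_test(series: OESeries) -> HeterogeneityResult:
    """Likelihood-ratio test that the twelve monthly SIRs are equal.

    LR = 2 * sum_m O_m log(O_m / (c E_m)) with c = sum O / sum E (so the
    statistic is invariant to a global rescaling of E), df = 11, p from the
    chi-square upper tail. The 0 log 0 = 0 convention handles empty months.
    """
    O = series.observed.astype(float)
    E = series.expected
    if O.sum() <= 0:
        raise ValueError("heterogeneity test needs at least one observed case")
    if np.count_nonzero(E) < 2:
        raise ValueError("heterogeneity test needs at least two periods with "
                         "positive expected counts")
    if np.any(E <= 0):
        raise ValueError("every monthly expected count must be positive")
    c = O.sum() / E.sum()
    terms = np.where(O > 0, O * np.log(np.where(O > 0, O, 1.0) / (c * E)), 0.0)
    lr = float(2.0 * terms.sum())
    lr = max(lr, 0.0)
    df = N_PERIODS - 1
    return HeterogeneityResult(lr, df, float(chi2.sf(lr, df)))


def window_sir(series: OESeries, window, alpha: float = 0.05,
               ci_method: str = "profile") -> tuple[SIREstimate, SIREstimate]:
    """SIRs inside and outside a contiguous circular window of months.

    ``window`` is a :class:`seasonscan.scan.Window` (or anything with
    ``members()``); the two estimates partition the loop, so their O (and E)
    add up to the series totals.
    """
    members = list(window.members())
    if not 1 <= len(members) <= N_PERIODS - 1:
        raise ValueError("window must cover between 1 and 11 periods")
    idx = np.array([m - 1 for m in members])
    mask = np.zeros(N_PERIODS, dtype=bool)
    mask[idx] = True
    o_in = int(series.observed[mask].sum())
    e_in = float(series.expected[mask].sum())
    o_out = int(series.observed[~mask].sum())
    e_out = float(series.expected[~mask].sum())
    label_in = window.label(scheme=series.scheme)
    label_out = window.complement_label(scheme=series.scheme)
    return (sir_estimate(o_in, e_in, alpha, label_in, ci_method),
            sir_estimate(o_out, e_out, alpha, label_out, ci_method))
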