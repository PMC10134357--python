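"""Circular (seasonal) Poisson scan statistic with Monte-Carlo inference.

The twelve periods form a loop (December adjoins January). Every contiguous
window of 1..max_len periods is a cluster candidate; each is scored by the
Poisson log-likelihood ratio comparing distinct rates inside and outside the
window against a single homogeneous rate. The maximum over candidates is the
test statistic and its window is the most likely cluster — an excess or a
deficit, both are admissible in one sweep.

Significance is Monte Carlo: conditioning on the total count, each replicate
redistributes the N observed cases over the periods multinomially with
probabilities E_m / sum E, the max-LLR is recomputed, and the p-value is the
(r+1)/(nsim+1) rank of the observed statistic (ties count against rejection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import MONTH_ABBR, N_PERIODS, OESeries
from .sir import SIREstimate, window_sir


@dataclass(frozen=True)
class Window:
    """A contiguous circular set of periods: ``start`` (1..12) and ``length``."""

    start: int
    length: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= N_PERIODS:
            raise ValueError(f"start must be 1..12, got {self.start}")
        if not 1 <= self.length <= N_PERIODS - 1:
            raise ValueError(f"length must be 1..11, got {self.length}")

    def members(self) -> list[int]:
        return [(self.start - 1 + k) % N_PERIODS + 1 for k in range(self.length)]

    def __contains__(self, period: int) -> bool:
        return period in self.members()

    def label(self, scheme: str = "calendar") -> str:
        m = self.members()
        if scheme == "midmonth":
            first, last = m[0], m[-1] % N_PERIODS + 1
            return f"15 {MONTH_ABBR[first - 1]}-14 {MONTH_ABBR[last - 1]}"
        if self.length == 1:
            return MONTH_ABBR[m[0] - 1]
        return f"{MONTH_ABBR[m[0] - 1]}-{MONTH_ABBR[m[-1] - 1]}"

    def complement(self) -> "Window":
        return Window(self.members()[-1] % N_PERIODS + 1, N_PERIODS - self.length)

    def complement_label(self, scheme: str = "calendar") -> str:
        return self.complement().label(scheme=scheme)


@dataclass(frozen=True)
class ScanResult:
    window: Window
    o_in: int
    e_in: float
    o_out: int
    e_out: float
    sir_in: SIREstimate
    sir_out: SIREstimate
    llr: float
    direction: str  # "high" or "low"
    p_value: float | None = None
    nsim: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "window": {"start": self.window.start, "length": self.window.length,
                       "label": self.sir_in.label},
            "o_in": self.o_in, "e_in": self.e_in,
            "o_out": self.o_out, "e_out": self.e_out,
            "sir_in": self.sir_in.to_dict(), "sir_out": self.sir_out.to_dict(),
            "llr": self.llr, "direction": self.direction,
            "p_value": self.p_value, "nsim": self.nsim, "seed": self.seed,
        }


def enumerate_windows(max_len: int = 6) -> list[Window]:
    """All candidate windows: 12 starts x max_len lengths, shortest first."""
    if not 1 <= max_len <= N_PERIODS - 1:
        raise ValueError(f"max_len must be 1..11, got {max_len}")
    return [Window(start, length)
            for length in range(1, max_len + 1)
            for start in range(1, N_PERIODS + 1)]


def window_llr(o_in: float, e_in: float, o_tot: float, e_tot: float) -> float:
    """Poisson log-likelihood ratio for one in/out split of the loop.

    llr = O_in log(O_in/E_in) + O_out log(O_out/E_out) - O_tot log(O_tot/E_tot)
    with 0 log 0 = 0; non-negative, and 0 when the in/out rates are equal.
    """
    if not 0 <= o_in <= o_tot:
        raise ValueError("need 0 <= o_in <= o_tot")
    if not 0 < e_in < e_tot:
        raise ValueError("need 0 < e_in < e_tot")
    o_out, e_out = o_tot - o_in, e_tot - e_in

    def xlogx(o: float, e: float) -> float:
        return o * np.log(o / e) if o > 0 else 0.0

    return max(xlogx(o_in, e_in) + xlogx(o_out, e_out) - xlogx(o_tot, e_tot), 0.0)


def _window_matrix(max_len: int) -> np.ndarray:
    """(n_windows, 12) 0/1 membership matrix in enumerate_windows order."""
    wins = enumerate_windows(max_len)
    mat = np.zeros((len(wins), N_PERIODS))
    for i, w in enumerate(wins):
        mat[i, [m - 1 for m in w.members()]] = 1.0
    return mat


def _all_llrs(obs: np.ndarray, expected: np.ndarray, wmat: np.ndarray) -> np.ndarray:
    """Vectorised LLR of every candidate window for one or many count vectors.

    ``obs`` has shape (..., 12); returns shape (..., n_windows).
    """
    o_in = obs @ wmat.T
    e_in = expected @ wmat.T
    o_tot = obs.sum(axis=-1, keepdims=True)
    e_tot = expected.sum()

    def xlogx(o, e):
        with np.errstate(divide="ignore", invalid="ignore"):
            v = o * np.log(o / e)
        return np.where(o > 0, v, 0.0)

    llr = xlogx(o_in, e_in) + xlogx(o_tot - o_in, e_tot - e_in) - xlogx(o_tot, e_tot)
    return np.maximum(llr, 0.0)


def most_likely_cluster(series: OESeries, max_len: int = 6,
                        alpha: float = 0.05, ci_method: str = "profile") -> ScanResult:
    """The window maximising the LLR (excess or deficit), p-value unset.

    Ties are broken towards the shorter window, then the earlier start —
    ``enumerate_windows`` order makes the first maximum the winner.
    """
    if series.total_observed <= 0:
        raise ValueError("scan needs at least one observed case")
    if np.any(series.expected <= 0):
        raise ValueError("scan needs positive expected counts in every period")
    wins = enumerate_windows(max_len)
    wmat = _window_matrix(max_len)
    llrs = _all_llrs(series.observed.astype(float), series.expected, wmat)
    best = int(np.argmax(llrs > llrs.max() - 1e-12))  # first within tolerance of max
    w = wins[best]
    sir_in, sir_out = window_sir(series, w, alpha=alpha, ci_method=ci_method)
    direction = "high" if sir_in.sir >= sir_out.sir else "low"
    return ScanResult(w, sir_in.observed, sir_in.expected, sir_out.observed,
                      sir_out.expected, sir_in, sir_out, float(llrs[best]), direction)


def monte_carlo_p(series: OESeries, observed_llr: float, nsim: int = 9999,
                  seed: int | None = None, max_len: int = 6,
                  batch: int = 100_000) -> float:
    """Monte-Carlo p-value of an observed max-LLR under the homogeneous null.

    Replicates condition on the total: N cases are thrown over the 12 periods
    multinomially with probabilities E/sum E. p = (1 + #{llr_sim >=
    llr_obs}) / (nsim + 1); the smallest attainable value is 1/(nsim+1).
    """
    if nsim < 1:
        raise ValueError("nsim must be at least 1")
    rng = np.random.default_rng(seed)
    n = series.total_observed
    probs = series.expected / series.total_expected
    wmat = _window_matrix(max_len)
    exceed = 0
    done = 0
    while done < nsim:
        k = min(batch, nsim - done)
        sims = rng.multinomial(n, probs, size=k).astype(float)
        mx = _all_llrs(sims, series.expected, wmat).max(axis=-1)
        exceed += int(np.sum(mx >= observed_llr - 1e-12))
        done += k
    return (1 + exceed) / (nsim + 1)


def scan(series: OESeries, max_len: int = 6, nsim: int = 9999,
         seed: int | None = None, alpha: float = 0.05,
         ci_method: str = "profile") -> ScanResult:
    """Full seasonal scan: most likely cluster plus its Monte-Carlo p-value."""
    result = most_likely_cluster(series, max_len=max_len, alpha=alpha, ci_method=ci_method)
    p = monte_carlo_p(series, result.llr, nsim=nsim, seed=seed, max_len=max_len)
    return ScanResult(result.window, result.o_in, result.e_in, result.o_out,
                      result.e_out, result.sir_in, result.sir_out, result.llr,
                      result.direction, p_value=p, nsim=nsim, seed=seed)
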