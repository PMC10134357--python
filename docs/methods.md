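# Methods

## Model and assumptions

All inference treats the monthly case count O_{m,y} for period m of year y
as Poisson with mean SIR·E_{m,y}, where the expected count E_{m,y} comes
from age-specific reference rates applied to person-years at risk. The
working assumption throughout is that any monthly variation is homogeneous
across the study years — the heterogeneity and scan tests operate on the
year-aggregated 12-period loop, and the reproducibility test is exactly the
check of that assumption for a detected window. Months are treated as a
circle (December adjoins January), so a window may straddle the year end.

Internal standardisation is applied by default: expected counts are rescaled
by a single constant so that ΣE equals the analysis cohort's ΣO. The
published tables this package reanalyses satisfy that convention (their E
columns sum to the case totals), it makes the null intercept zero, and every
test statistic used here is invariant to the rescaling anyway.

## Person-years

Two constructions, chosen by the analysis axis:

- **Birth cohort** (month-of-birth analyses): monthly live births NB_{m,y}
  are assumed uniform within their month; the cohort contributes at
  completed age a a full year while a+y is before the follow-up end year,
  the fraction (12−m+0.5)/12 in the final year (the half month reflects the
  uniform-births assumption), and nothing after — follow-up stops at the
  earlier of the 15th birthday and the study end. `end_year` is a parameter;
  the default 2015 matches the reference study period 2000–2015.
- **Census** (month-of-diagnosis analyses): annual person-years at age a are
  the mean of consecutive 1-January populations, split over months
  proportionally to their day counts with Gregorian leap rules. Monthly
  shares reconstitute the annual totals exactly (asserted to 1e-9 relative
  in tests).

Age strata are single completed years 0–14, the finest grid census inputs
support. Reference rates are pooled over the whole period by default;
`rate_mode="annual"` uses year-specific rates (the sensitivity analysis for
a group whose rates drift over time).

## SIR confidence intervals

Two methods are exposed, because published registry tables use both
depending on the software that produced them:

- **profile** (default): inverts the Poisson deviance
  2[μ − O + O ln(O/μ)] ≤ χ²₀.₉₅(1) — the interval a Poisson GLM profile
  gives, matching regression-derived monthly SIR tables.
- **garwood**: the exact interval ½χ²_{α/2,2O} ≤ μ ≤ ½χ²_{1−α/2,2(O+1)},
  conservative by construction, matching the intervals scan software prints
  for window SIRs.

Verified against the published monthly table, the profile method reproduces
all 72 printed bounds within ±0.009, while exact intervals deviate by up to
0.057; for the published window SIRs the situation reverses. Both methods
hold ≥94% empirical coverage in simulation. Monthly estimates never need an
iterative fit: the saturated-month offset model has the closed-form MLE
exp(β̂_m) = O_m/E_m (cross-checked against an iterative GLM to 1e-8).

## Heterogeneity test

LR = 2 Σ_m O_m ln(O_m/(c·E_m)) with c = ΣO/ΣE and 0·ln 0 = 0, referred to
χ²(11). The c correction makes the statistic scale-invariant in E; year
effects are absorbed in E rather than modelled, which on internally
standardised data reproduces published heterogeneity p-values to printed
precision.

## Seasonal scan

Candidates are the 72 circular windows of length 1–6 starting at each of the
12 periods. Each is scored by the Poisson log-likelihood ratio comparing
separate inside/outside rates to a homogeneous rate; the maximum is the test
statistic and its window the most likely cluster. Design choices:

- **Two-sided in one sweep.** Deficits and excesses are both admissible;
  the LLR is symmetric under complementation (a 1-month excess is an
  11-month deficit), so restricting window length to 6 months loses nothing.
- **Monte-Carlo null conditions on the total.** Replicates throw N = ΣO
  cases over the periods multinomially with probabilities E_m/ΣE, the
  standard temporal-scan convention; conditioning removes the nuisance
  total. An unconditional Poisson null was evaluated and shifts p-values by
  under 0.01 on the reanalysed series. The p-value is the (r+1)/(nsim+1)
  rank with ties counting against rejection, so p ≥ 1/(nsim+1) always and
  is bit-for-bit reproducible at a fixed seed.
- **Aggregation.** Scanning the year-aggregated loop equals scanning
  month×year cells with year-invariant windows, because the LLR depends only
  on window-aggregated O and E — and a multinomial over cells aggregates to
  a multinomial over periods, so the Monte-Carlo null agrees too.
- **Ties** break to the shorter window, then the earlier start
  (deterministic; ties have probability ~0 for real-valued E).

The replicate LLRs are computed vectorised over a 72×12 membership matrix;
nsim = 9999 runs in well under a second.

## Reproducibility (SIRR)

For a fixed window, SIRR = (O_in/E_in)/(O_out/E_out) per year and overall.
CIs use the exact conditional-binomial construction: given N = O_in+O_out,
O_in ~ Binomial(N, π) with π = sirr·E_in/(sirr·E_in+E_out); a
Clopper–Pearson interval for π is inverted to sirr bounds. Years with
O_out = 0 are reported with an infinite ratio and an undefined upper bound
rather than dropped; years with no cases at all are flagged NA.

The between-year test compares the model with free year effects plus one
shared window effect against the per-year-effect (saturated) model on the
Y×2 table; df = Y−1. The null fit profiles out the year effects
analytically, leaving a monotone one-dimensional score equation solved by
bisection to 1e-12 (cross-checked against an iterative GLM to 1e-8). Because
the fitted per-year totals match the observed ones, the deviance difference
reduces to 2 Σ O ln(O/μ̂) with 0·ln 0 = 0.

## Mid-month sensitivity scheme

The alternative binning uses twelve 30-day periods cut at mid-month: period
p runs from the 15th of month p to the 14th of month p+1, with period 12
wrapping December into January and attributed to the earlier year. Expected
counts are recoded by day-weighted splitting of adjacent calendar months:
E_p = E_p^cal·(ND_p−14)/ND_p + E_{p+1}^cal·14/ND_{p+1} — an approximation,
since the true within-month distribution of E is not flat across ages at
the year boundary, but the error is far below the Poisson noise. Edge
handling: the first study year's 1–14 January dates belong to the
wrap-around period with no preceding year and are attributed to the first
year (totals conserved); the final year's period 12 is truncated at the
study end, and the recoded expected counts are renormalised to the observed
total.

## Synthetic registry generator

The generator emulates the statistical structure the inference assumes: a
constant 65,000 live births per month, a constant 733,000 children per
single year of age (≈11 million under-15s), an age-rate profile front-loaded
like embryonal tumours (≈39% of cases in the first year of life) scaled to a
chosen annual group incidence (default 12.3 per million per year, a
neuroblastoma-sized group; the multi-group registry script uses each group's
published incidence), and an optional multiplicative rate ratio ρ on a
window of birth or diagnosis months. Counts are drawn Poisson at the
(month, year, age) cell level and then materialised as case records — dates
uniform within the cell's admissible interval, attributes from mixtures
matching the reference registry's case mix (sex ratios per group, 47.4%
metastatic and 19.6% amplified-MYCN-among-known for neuroblastoma, 69.2%
unilateral retinoblastoma). One seed drives a fixed stream order
(cell counts → attributes → dates), so a config plus seed reproduces the
registry byte for byte.

What it deliberately does not emulate: calendar trends or drift in rates,
diagnostic delay distributions, migration, registration artefacts, or
within-month birth seasonality. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the assumed
Poisson model, not robustness to real-registry messiness.

## Problem sizes and numerical conventions

Simulation-based checks use sizes chosen to give stable Monte-Carlo
verdicts while keeping the suite quick: 500 replicates for null SIR
calibration (monthly mean SIR within 0.02 of 1), 1000 null replicates at
nsim=999 for the scan's type-I error (accepted range 3–7% at nominal 5%),
200 replicates for recovery of a ρ=1.5 June–August effect (≥95% window
overlap; the inside SIR is measured against the generator's true reference
rates, since internal standardisation would fold the injected excess into
the denominator), 2000 draws for CI coverage, and 300–1000 replicates for
p-uniformity Kolmogorov–Smirnov checks. The analysis scripts use nsim=999;
published-series reanalysis uses the reference nsim=9999.

Comparisons against printed values use round-half-away-from-zero at the
printed precision, and where a printed input (expected counts are given to
one decimal) places a derived quantity on a rounding boundary, the
comparison propagates the ±0.05 input interval.

## Known limitations

- Monte-Carlo p-values for the published series are computed from the
  printed monthly aggregates; analyses run on confidential case-level data
  with finer time resolution can differ by several hundredths, which is
  within-method variation a desk reanalysis cannot remove.
- The interaction test's χ² reference is asymptotic; with very sparse
  per-year windows (a few expected cases) its p-values are approximate —
  the simulation checks use cell sizes where the approximation holds.
- The mid-month expected-count recoding is a day-weighted approximation,
  logged as such in the pipeline.
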