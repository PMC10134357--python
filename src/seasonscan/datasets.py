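"""Published monthly observed/expected series for French childhood embryonal
tumours, mainland France, 2000-2015.

These are the national childhood cancer registry aggregates by month of
birth (six diagnostic groups, whole study period) together with the window
totals reported for the subgroup and month-of-diagnosis analyses. Expected
counts are internally standardised (column totals equal the case totals up to
the 1-decimal rounding of the source tables). They are inputs to this
package's reanalysis scripts and tests — the finest-grained public form of
the registry data.
"""

from __future__ import annotations

import numpy as np

from .series import OESeries

#: month-of-birth (O, E) by diagnostic group; periods are calendar months Jan..Dec
BIRTH_MONTH_SERIES: dict[str, dict[str, list]] = {
    "neuroblastoma": {
        "observed": [165, 137, 157, 142, 158, 163, 143, 149, 147, 187, 145, 146],
        "expected": [159.0, 144.0, 153.9, 149.5, 157.4, 151.7,
                     161.6, 156.9, 153.3, 155.7, 146.6, 149.5],
    },
    "nephroblastoma": {
        "observed": [74, 94, 95, 88, 91, 86, 96, 98, 96, 88, 81, 86],
        "expected": [93.2, 84.4, 90.1, 87.6, 92.1, 88.6,
                     94.3, 91.3, 89.1, 90.5, 85.1, 86.7],
    },
    "medulloblastoma": {
        "observed": [45, 45, 38, 36, 52, 37, 49, 51, 48, 44, 47, 49],
        "expected": [47.7, 43.1, 45.9, 44.6, 46.8, 44.7,
                     47.5, 45.8, 44.5, 45.1, 42.3, 43.0],
    },
    "rhabdomyosarcoma": {
        "observed": [53, 37, 40, 43, 55, 59, 51, 56, 60, 48, 50, 47],
        "expected": [52.4, 47.4, 50.6, 49.1, 51.6, 49.5,
                     52.6, 50.9, 49.5, 50.3, 47.2, 48.0],
    },
    "retinoblastoma": {
        "observed": [59, 60, 62, 54, 51, 60, 66, 62, 60, 68, 38, 58],
        "expected": [60.2, 54.5, 58.3, 56.6, 59.6, 57.6,
                     61.3, 59.6, 58.3, 59.2, 55.8, 56.9],
    },
    "hepatoblastoma": {
        "observed": [23, 18, 20, 19, 19, 16, 16, 14, 14, 19, 13, 15],
        "expected": [17.8, 16.1, 17.2, 16.7, 17.6, 17.0,
                     18.1, 17.6, 17.2, 17.4, 16.4, 16.8],
    },
}

#: published monthly SIR point estimates (month of birth), for cross-checks
BIRTH_MONTH_SIRS: dict[str, list[float]] = {
    "neuroblastoma": [1.04, 0.95, 1.02, 0.95, 1.00, 1.07, 0.88, 0.95, 0.96, 1.20, 0.99, 0.98],
    "nephroblastoma": [0.79, 1.11, 1.05, 1.00, 0.99, 0.97, 1.02, 1.07, 1.08, 0.97, 0.95, 0.99],
    "medulloblastoma": [0.94, 1.04, 0.83, 0.81, 1.11, 0.83, 1.03, 1.11, 1.08, 0.98, 1.11, 1.14],
    "rhabdomyosarcoma": [1.01, 0.78, 0.79, 0.88, 1.07, 1.19, 0.97, 1.10, 1.21, 0.96, 1.06, 0.98],
    "retinoblastoma": [0.98, 1.10, 1.06, 0.95, 0.86, 1.04, 1.08, 1.04, 1.03, 1.15, 0.68, 1.02],
    "hepatoblastoma": [1.29, 1.12, 1.16, 1.13, 1.08, 0.94, 0.88, 0.80, 0.82, 1.09, 0.79, 0.89],
}

#: published 95% CIs for the monthly SIRs (month of birth)
BIRTH_MONTH_CIS: dict[str, list[tuple[float, float]]] = {
    "neuroblastoma": [(0.89, 1.20), (0.80, 1.12), (0.87, 1.19), (0.80, 1.11),
                      (0.86, 1.17), (0.92, 1.25), (0.75, 1.04), (0.81, 1.11),
                      (0.81, 1.12), (1.04, 1.38), (0.84, 1.16), (0.83, 1.14)],
    "nephroblastoma": [(0.63, 0.99), (0.90, 1.35), (0.86, 1.28), (0.81, 1.23),
                       (0.80, 1.21), (0.78, 1.19), (0.83, 1.24), (0.87, 1.30),
                       (0.88, 1.31), (0.78, 1.19), (0.76, 1.17), (0.80, 1.22)],
    "medulloblastoma": [(0.69, 1.25), (0.77, 1.38), (0.59, 1.12), (0.57, 1.10),
                        (0.84, 1.44), (0.59, 1.12), (0.77, 1.35), (0.84, 1.45),
                        (0.80, 1.41), (0.71, 1.29), (0.82, 1.46), (0.85, 1.49)],
    "rhabdomyosarcoma": [(0.76, 1.31), (0.56, 1.06), (0.57, 1.06), (0.64, 1.16),
                         (0.81, 1.37), (0.91, 1.52), (0.73, 1.26), (0.84, 1.42),
                         (0.93, 1.54), (0.71, 1.25), (0.79, 1.38), (0.72, 1.29)],
    "retinoblastoma": [(0.75, 1.25), (0.84, 1.40), (0.82, 1.35), (0.72, 1.23),
                       (0.64, 1.11), (0.80, 1.33), (0.84, 1.36), (0.80, 1.32),
                       (0.79, 1.31), (0.90, 1.44), (0.49, 0.92), (0.78, 1.30)],
    "hepatoblastoma": [(0.83, 1.90), (0.68, 1.71), (0.72, 1.75), (0.70, 1.72),
                       (0.66, 1.64), (0.55, 1.48), (0.52, 1.39), (0.45, 1.29),
                       (0.46, 1.32), (0.67, 1.65), (0.44, 1.30), (0.51, 1.43)],
}

#: published heterogeneity-test p-values by group (month of birth)
BIRTH_MONTH_P_HET: dict[str, float] = {
    "neuroblastoma": 0.46, "nephroblastoma": 0.80, "medulloblastoma": 0.74,
    "rhabdomyosarcoma": 0.48, "retinoblastoma": 0.49, "hepatoblastoma": 0.92,
}

#: published most likely cluster (month of birth): window label, start, length,
#: O_in, E_in, inside SIR, Monte-Carlo p
BIRTH_MONTH_CLUSTERS: dict[str, dict] = {
    "neuroblastoma": {"label": "Oct", "start": 10, "length": 1,
                      "o_in": 187, "e_in": 155.7, "sir_in": 1.20, "p": 0.30},
    "nephroblastoma": {"label": "Jan", "start": 1, "length": 1,
                       "o_in": 74, "e_in": 93.2, "sir_in": 0.79, "p": 0.46},
    "medulloblastoma": {"label": "Mar-Apr", "start": 3, "length": 2,
                        "o_in": 74, "e_in": 90.6, "sir_in": 0.82, "p": 0.63},
    "rhabdomyosarcoma": {"label": "Feb-Apr", "start": 2, "length": 3,
                         "o_in": 120, "e_in": 147.1, "sir_in": 0.82, "p": 0.32},
    "retinoblastoma": {"label": "Nov", "start": 11, "length": 1,
                       "o_in": 38, "e_in": 55.8, "sir_in": 0.68, "p": 0.22},
    "hepatoblastoma": {"label": "Jan-May", "start": 1, "length": 5,
                       "o_in": 99, "e_in": 85.5, "sir_in": 1.16, "p": 0.63},
}

#: window totals published for subgroup / month-of-diagnosis analyses:
#: (O_in, E_in, O_out, E_out) plus the reported SIRs and CIs
WINDOW_TOTALS: dict[str, dict] = {
    "rhabdomyosarcoma_boys_birth_jun_sep": {
        "window": (6, 4), "o_in": 153, "e_in": 123.2, "o_out": 211, "e_out": 240.8,
        "sir_in": 1.24, "ci_in": (1.05, 1.46), "sir_out": 0.88, "ci_out": (0.76, 1.00),
    },
    "retinoblastoma_unilateral_dx_jul_aug": {
        "window": (7, 2), "o_in": 64, "e_in": 94.4, "o_out": 492, "e_out": 461.6,
        "sir_in": 0.68, "ci_in": (0.52, 0.87),
    },
    "rhabdomyosarcoma_dx_aug": {
        "window": (8, 1), "o_in": 56, "e_in": 81.8, "o_out": 908, "e_out": 882.2,
        "sir_in": 0.68, "ci_in": (0.52, 0.89), "sir_out": 1.03, "ci_out": (0.96, 1.10),
    },
    "retinoblastoma_dx_jun_aug": {
        "window": (6, 3), "o_in": 152, "e_in": 202.5, "o_out": 652, "e_out": 601.5,
        "sir_in": 0.75, "ci_in": (0.64, 0.88), "sir_out": 1.08, "ci_out": (1.00, 1.17),
    },
}

GROUPS = tuple(BIRTH_MONTH_SERIES)


def birth_month_series(group: str) -> OESeries:
    """The month-of-birth (O, E) loop for one diagnostic group."""
    try:
        d = BIRTH_MONTH_SERIES[group]
    except KeyError:
        raise KeyError(f"unknown group {group!r}; choose from {GROUPS}") from None
    return OESeries(np.array(d["observed"]), np.array(d["expected"]))
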