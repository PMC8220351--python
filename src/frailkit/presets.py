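"""Published reference estimates used to calibrate the synthetic cohort.

The numbers here are the headline estimates of a population-representative
Irish longitudinal study of ageing (adults aged 65+, five roughly biennial
waves): the fitted 2-year transition-probability matrix between the
collapsed frailty states, the final-wave CFS category prevalence, and the
category-conditional means of the health and social-care utilisation
variables.  They serve as ground-truth calibration targets for the
simulator, so recovery experiments run at realistic parameter values.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "REFERENCE_P2",
    "reference_generator",
    "CFS_PREVALENCE_PCT",
    "category_probs",
    "SERVICE_NAMES",
    "COUNT_VARIABLES",
    "CARE_TYPES",
    "default_utilisation_params",
]

#: Published mean 2-year transition probabilities between the collapsed
#: states (fit, vulnerable, frail, died); rows as printed (they round to
#: within 0.01 of stochastic).
REFERENCE_P2 = np.array(
    [
        [0.59, 0.34, 0.06, 0.02],
        [0.22, 0.57, 0.16, 0.05],
        [0.06, 0.17, 0.51, 0.25],
        [0.00, 0.00, 0.00, 1.00],
    ]
)

#: Final-wave CFS category prevalence (percent), CFS1..CFS7; rounding makes
#: the printed vector sum to 99.5.
CFS_PREVALENCE_PCT = np.array([6.0, 36.0, 31.0, 16.0, 5.5, 4.3, 0.7])


def category_probs() -> np.ndarray:
    """CFS1-7 baseline category probabilities (prevalence renormalised)."""
    p = CFS_PREVALENCE_PCT / CFS_PREVALENCE_PCT.sum()
    return p


@lru_cache(maxsize=1)
def _reference_generator_cached():
    from .msm import nearest_generator

    P = REFERENCE_P2 / REFERENCE_P2.sum(axis=1, keepdims=True)
    return nearest_generator(P, t=2.0)


def reference_generator() -> np.ndarray:
    """Generator matrix calibrated to :data:`REFERENCE_P2` (2-year lag).

    Obtained as the clipped principal matrix logarithm of the row-renormalised
    reference matrix; reproduces it to within ~0.006 per entry.
    """
    return _reference_generator_cached().Q.copy()


#: The 13 state-provided community services surveyed as yes/no use.
SERVICE_NAMES: tuple[str, ...] = (
    "physiotherapy",
    "occupational_therapy",
    "public_health_nurse",
    "dietician",
    "hearing",
    "dental",
    "optician",
    "psychological_counselling",
    "social_work",
    "speech_language",
    "chiropody",
    "day_centre",
    "respite",
)

#: Annual medical utilisation count variables.
COUNT_VARIABLES: tuple[str, ...] = (
    "gp_visits",
    "outpatient_visits",
    "ed_visits",
    "admissions",
    "hospital_nights",
)

#: Care provider types whose hours/day and days/month are surveyed.
CARE_TYPES: tuple[str, ...] = ("informal_unpaid", "paid_nonstate", "formal_state")

# Category-conditional means (CFS1..CFS7) of the annual medical utilisation
# counts; endpoints are the published category means (GP 2.5->5.9,
# outpatient 0.7->3.9, ED 0.1->0.9, admissions 0.2->1.0, nights 6.6->26.1,
# with the published dip for GP/nights at CFS7); interior values
# interpolated.
_COUNT_MEANS = {
    "gp_visits": [2.5, 3.0, 3.6, 4.3, 5.1, 6.5, 5.9],
    "outpatient_visits": [0.7, 1.0, 1.4, 1.9, 2.5, 3.2, 3.9],
    "ed_visits": [0.1, 0.18, 0.27, 0.38, 0.52, 0.7, 0.9],
    "admissions": [0.2, 0.28, 0.38, 0.5, 0.64, 0.8, 1.0],
    "hospital_nights": [6.6, 8.0, 10.0, 12.5, 16.0, 29.0, 26.1],
}

# Mean total services received per category (published: 0.3 at CFS1 rising
# to 2.0 at CFS7); split across the 13 services with fixed relative weights
# (nursing, chiropody and day-centre/respite services dominate at high CFS).
_SERVICES_TOTAL_MEAN = np.array([0.3, 0.45, 0.65, 0.9, 1.2, 1.6, 2.0])
_SERVICE_WEIGHTS = np.array(
    [0.10, 0.08, 0.16, 0.05, 0.05, 0.08, 0.08, 0.05, 0.05, 0.05, 0.10, 0.08, 0.07]
)

# Care receipt probability and conditional hours/day, days/month per
# provider type and category; calibrated so monthly formal-state hours rise
# from ~1 (CFS1) to ~24 (CFS6) with a dip at CFS7, and informal unpaid care
# dominates at high frailty.
_CARE_DEFAULTS = {
    "informal_unpaid": {
        "receipt_prob": [0.05, 0.08, 0.12, 0.25, 0.60, 0.75, 0.90],
        "hours_per_day": [1.0, 1.0, 1.2, 1.5, 2.5, 3.5, 5.0],
        "days_per_month": [4.0, 5.0, 6.0, 8.0, 16.0, 20.0, 26.0],
    },
    "paid_nonstate": {
        "receipt_prob": [0.01, 0.02, 0.03, 0.06, 0.0, 0.25, 0.40],
        "hours_per_day": [1.0, 1.0, 1.0, 1.5, 1.5, 2.5, 3.0],
        "days_per_month": [4.0, 4.0, 5.0, 6.0, 8.0, 12.0, 16.0],
    },
    "formal_state": {
        "receipt_prob": [0.03, 0.05, 0.08, 0.12, 0.45, 0.55, 0.50],
        "hours_per_day": [1.0, 1.0, 1.2, 1.5, 2.0, 2.2, 2.0],
        "days_per_month": [5.0, 5.0, 6.0, 7.0, 11.0, 14.0, 12.0],
    },
}


def default_utilisation_params():
    """Default category-conditional utilisation distributions (CFS1..CFS7)."""
    from .simulate import CareParams, UtilisationParams

    service_probs = np.clip(
        np.outer(_SERVICE_WEIGHTS, _SERVICES_TOTAL_MEAN), 0.0, 1.0
    )
    return UtilisationParams(
        count_means={k: np.array(v, dtype=float) for k, v in _COUNT_MEANS.items()},
        count_dispersion={k: None for k in _COUNT_MEANS},
        service_probs=service_probs,
        care={
            name: CareParams(
                receipt_prob=np.array(d["receipt_prob"], dtype=float),
                hours_per_day_mean=np.array(d["hours_per_day"], dtype=float),
                days_per_month_mean=np.array(d["days_per_month"], dtype=float),
            )
            for name, d in _CARE_DEFAULTS.items()
        },
    )
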