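"""Survey-weighted cross-sectional summaries of care utilisation by CFS category.

Estimates use attrition weights so means and proportions represent the
community-dwelling population aged 65+.  The weighted mean is the ratio
estimator sum(w*x)/sum(w); its standard error uses the standard
design-based linearisation

    SE^2 = n/(n-1) * sum_i [ w_i (x_i - xbar_w) ]^2 / (sum_i w_i)^2,

which reduces to the usual SE under equal weights, and 95% intervals use
the normal quantile (z = 1.96).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import presets

__all__ = [
    "SummaryRow",
    "weighted_mean_ci",
    "services_count",
    "monthly_care_hours",
    "fold_change",
    "summarize_panel",
]


@dataclass(frozen=True)
class SummaryRow:
    variable: str
    cfs_category: int | None
    estimate: float
    ci_low: float
    ci_high: float
    n: int


def weighted_mean_ci(values, weights, conf: float = 0.95,
                     variable: str = "", cfs_category: int | None = None) -> SummaryRow:
    """Survey-weighted mean with a design-based normal CI.

    Requires at least two observations and positive total weight; the point
    estimate is scale-equivariant and invariant to rescaling all weights.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1:
        raise ValueError("values and weights must be equal-length vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("total weight must be positive")
    mean = float(w @ x / wsum)
    n = len(x)
    se = float(np.sqrt(n / (n - 1) * np.sum((w * (x - mean)) ** 2)) / wsum)
    z = stats.norm.ppf(0.5 + conf / 2)
    return SummaryRow(
        variable=variable,
        cfs_category=cfs_category,
        estimate=mean,
        ci_low=mean - z * se,
        ci_high=mean + z * se,
        n=n,
    )


def services_count(flags: Sequence) -> int:
    """Count of community services used out of the 13 surveyed (yes/no each)."""
    flags = list(flags)
    if len(flags) != len(presets.SERVICE_NAMES):
        raise ValueError(
            f"expected {len(presets.SERVICE_NAMES)} service flags, got {len(flags)}"
        )
    return int(sum(bool(f) for f in flags))


def monthly_care_hours(hours_per_day: float, days_per_month: float) -> float:
    """Monthly care hours for one provider: hours/day x days/month."""
    if hours_per_day < 0:
        raise ValueError(f"hours_per_day must be >= 0, got {hours_per_day}")
    if not 0 <= days_per_month <= 31:
        raise ValueError(f"days_per_month must be in [0, 31], got {days_per_month}")
    return float(hours_per_day) * float(days_per_month)


def fold_change(category_means) -> float:
    """Ratio of the highest (CFS7) to lowest (CFS1) category mean."""
    means = dict(category_means)
    if 1 not in means or 7 not in means:
        raise ValueError("need means for CFS1 and CFS7")
    lo = means[1]
    if not lo or not np.isfinite(lo):
        raise ValueError(f"CFS1 mean must be positive, got {lo!r}")
    return float(means[7]) / float(lo)


def summarize_panel(cohort: pd.DataFrame, wave_index: int | None = None,
                    variables: Sequence[str] | None = None,
                    conf: float = 0.95) -> pd.DataFrame:
    """Tidy weighted summary table by CFS category for one wave.

    Count and hours variables are summarised as weighted means, ``svc_*``
    flags as weighted proportions; a derived ``services_count`` and
    per-provider ``*_monthly_hours`` are added when their inputs are
    present.  Only respondents observed at the wave contribute.
    """
    df = cohort
    if wave_index is not None:
        df = df[df["wave_index"] == wave_index]
    df = df[df["status"] == "observed"] if "status" in df.columns else df
    df = df[df["cfs_category"].notna()].copy()

    svc_cols = [c for c in df.columns if c.startswith("svc_")]
    if svc_cols and "services_count" not in df.columns:
        df["services_count"] = df[svc_cols].astype(float).sum(axis=1)
    for ct in presets.CARE_TYPES:
        h, d = f"{ct}_hours_day", f"{ct}_days_month"
        if h in df.columns and d in df.columns:
            df[f"{ct}_monthly_hours"] = df[h].astype(float) * df[d].astype(float)

    if variables is None:
        variables = [
            *[v for v in presets.COUNT_VARIABLES if v in df.columns],
            *(["services_count"] if "services_count" in df.columns else []),
            *[f"{ct}_monthly_hours" for ct in presets.CARE_TYPES
              if f"{ct}_monthly_hours" in df.columns],
            *svc_cols,
        ]
    rows = []
    for cat, g in df.groupby(df["cfs_category"].astype(int)):
        for var in variables:
            sub = g[[var, "weight"]].dropna()
            if len(sub) < 2:
                continue
            rows.append(
                weighted_mean_ci(
                    sub[var].astype(float), sub["weight"].astype(float),
                    conf=conf, variable=var, cfs_category=int(cat),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
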