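"""Wave-to-wave flow tables: the numerical content of alluvial charts.

For each pair of consecutive waves the table counts subjects by (source
label, destination label), where labels are CFS categories (``CFS1`` ..)
or collapsed states plus ``died`` and ``missing``.  Missing is not
absorbing — subjects can skip a wave and return — while died is carried
forward, so the cumulative died proportion is non-decreasing and flows are
conserved at every wave boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tree import collapse_state

__all__ = ["flow_table", "wave_totals"]


def _labels(cohort: pd.DataFrame, level: str) -> pd.DataFrame:
    if level not in ("category", "state"):
        raise ValueError(f"level must be 'category' or 'state', got {level!r}")

    def lab(row) -> str:
        if row.status == "died":
            return "died"
        if row.status != "observed" or pd.isna(row.cfs_category):
            return "missing"
        c = int(row.cfs_category)
        return f"CFS{c}" if level == "category" else collapse_state(c)

    out = cohort[["subject_id", "wave_index"]].copy()
    out["label"] = [lab(r) for r in cohort.itertuples(index=False)]
    return out


def flow_table(cohort: pd.DataFrame, level: str = "state") -> pd.DataFrame:
    """Exact flow counts between consecutive waves.

    Returns a tidy frame (wave_from, wave_to, source, destination, count);
    subjects without a row at a wave are counted as ``missing`` there.
    """
    lab = _labels(cohort, level)
    wide = lab.pivot(index="subject_id", columns="wave_index", values="label")
    wide = wide.fillna("missing")
    waves = sorted(wide.columns)
    rows = []
    for w_from, w_to in zip(waves[:-1], waves[1:]):
        pairs = (
            wide.groupby(
                [wide[w_from].rename("source"), wide[w_to].rename("destination")],
                sort=True,
            )
            .size()
            .rename("count")
            .reset_index()
        )
        pairs.insert(0, "wave_to", w_to)
        pairs.insert(0, "wave_from", w_from)
        rows.append(pairs)
    return pd.concat(rows, ignore_index=True)


def wave_totals(cohort: pd.DataFrame, level: str = "state") -> pd.DataFrame:
    """Per-wave member counts by label (the stacked-bar heights)."""
    lab = _labels(cohort, level)
    wide = lab.pivot(index="subject_id", columns="wave_index", values="label").fillna("missing")
    out = []
    for w in sorted(wide.columns):
        counts = wide[w].value_counts()
        for label, n in counts.items():
            out.append({"wave_index": w, "label": label, "count": int(n)})
    return pd.DataFrame(out)
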