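"""Sample-accounting: ordered exclusion filters with an auditable ledger.

Analytical samples in longitudinal studies are defined by an ordered list
of exclusions (non-participation at the index wave, age restriction, not
present at baseline, missing scale data ...).  ``apply_filters`` applies
pure subject-level predicates in order and records, for each step, how many
subjects it removed and how many remain — the accounting that papers report
alongside their analytical sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["FilterLedger", "apply_filters", "synthetic_accounting_cohort"]

#: A filter: (description, predicate).  The predicate receives the current
#: panel and returns the subjects to KEEP as a boolean Series indexed by
#: subject_id (or any iterable of subject ids).
Filter = tuple[str, Callable[[pd.DataFrame], object]]


@dataclass
class FilterLedger:
    initial_n: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def final_n(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial_n

    def to_frame(self) -> pd.DataFrame:
        rows = [("initial sample", 0, self.initial_n)] + self.steps
        return pd.DataFrame(rows, columns=["filter", "n_removed", "n_remaining"])

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False)


def _keep_ids(panel: pd.DataFrame, result) -> set:
    if isinstance(result, pd.Series):
        if result.dtype == bool:
            return set(result[result].index)
        return set(result)
    return set(result)


def apply_filters(panel: pd.DataFrame, filters: Sequence[Filter]) -> tuple[pd.DataFrame, FilterLedger]:
    """Apply ordered subject-level exclusion filters to a cohort panel.

    Since predicates are pure (each subject's keep decision depends only on
    its own records), the final subject set is order-independent; the ledger
    is not.
    """
    current = panel
    ledger = FilterLedger(initial_n=current["subject_id"].nunique())
    n_prev = ledger.initial_n
    for desc, pred in filters:
        keep = _keep_ids(current, pred(current))
        current = current[current["subject_id"].isin(keep)]
        n_now = current["subject_id"].nunique()
        ledger.steps.append((desc, n_prev - n_now, n_now))
        n_prev = n_now
    return current.reset_index(drop=True), ledger


def synthetic_accounting_cohort(initial_n: int, removals: Sequence[tuple[str, int]]):
    """Build a synthetic one-row-per-subject panel realising given exclusion counts.

    For each (description, n_removed) step, exactly that many of the
    subjects still remaining get a True exclusion flag.  Returns the panel
    and the matching filter list for :func:`apply_filters` — a worked
    fixture for reproducing published sample-accounting arithmetic.
    """
    total_removed = sum(n for _, n in removals)
    if total_removed > initial_n:
        raise ValueError("cannot remove more subjects than the initial sample")
    panel = pd.DataFrame({"subject_id": np.arange(initial_n), "wave_index": 0})
    remaining = list(range(initial_n))
    filters: list[Filter] = []
    for i, (desc, n_removed) in enumerate(removals):
        col = f"excl_{i}"
        flagged = set(remaining[:n_removed])
        panel[col] = panel["subject_id"].isin(flagged)
        remaining = [s for s in remaining if s not in flagged]
        filters.append(
            (desc, lambda df, col=col: df.groupby("subject_id")[col].any().pipe(lambda s: ~s))
        )
    return panel, filters
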