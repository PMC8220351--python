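"""Shared fixtures: fixture trees, toy panels and independent oracles."""

from __future__ import annotations

import operator

import numpy as np
import pandas as pd
import pytest

from frailkit.items import EFFORT_LEVELS, SELF_RATED_HEALTH_LEVELS
from frailkit.tree import ItemDomain, TreeDefinition


@pytest.fixture
def leaf_tree():
    """Constant tree: every input scores CFS 3."""
    return TreeDefinition({"cfs": 3})


@pytest.fixture
def split_tree():
    """One split: any BADL help -> CFS 6, else CFS 2."""
    return TreeDefinition(
        {
            "item": "badl_help_count",
            "op": ">=",
            "value": 1,
            "children": {"yes": {"cfs": 6}, "no": {"cfs": 2}},
        }
    )


@pytest.fixture
def activity_tree():
    """Active in the past week -> CFS 1, else CFS 2."""
    return TreeDefinition(
        {
            "item": "active_past_week",
            "op": "==",
            "value": True,
            "children": {"yes": {"cfs": 1}, "no": {"cfs": 2}},
        }
    )


@pytest.fixture
def small_domain():
    """A deliberately small discretised domain for exhaustive sweeps."""
    return ItemDomain(badl_max=2, iadl_max=2, condition_max=3)


@pytest.fixture
def base_items():
    """A fully healthy item vector as a dict, to be perturbed per test."""
    return {
        "badl_help_count": 0,
        "iadl_help_count": 0,
        "condition_count": 0,
        "self_rated_health": "excellent",
        "effort_frequency": "rarely",
        "active_past_week": True,
    }


# ---------------------------------------------------------------------------
# independent path-walking oracle (kept deliberately separate in style and
# mechanics from the engine: ranks ordinals up front, dispatches through the
# operator module, recurses)

_RANKS = {
    "self_rated_health": {v: i for i, v in enumerate(SELF_RATED_HEALTH_LEVELS)},
    "effort_frequency": {v: i for i, v in enumerate(EFFORT_LEVELS)},
}
_OPFUNC = {
    "<": operator.lt,
    "<=": operator.le,
    ">=": operator.ge,
    ">": operator.gt,
    "==": operator.eq,
}


def oracle_classify(node: dict, items: dict) -> int:
    if "cfs" in node:
        return node["cfs"]
    name = node["item"]
    x = items[name]
    ref = node["value"]
    if node["op"] == "in":
        taken = x in list(ref)
    elif name in _RANKS:
        taken = _OPFUNC[node["op"]](_RANKS[name][x], _RANKS[name][ref])
    else:
        taken = _OPFUNC[node["op"]](x, ref)
    return oracle_classify(node["children"]["yes" if taken else "no"], items)


@pytest.fixture
def path_oracle():
    return oracle_classify


# ---------------------------------------------------------------------------
# toy observation panel: 3 subjects with a death and a skipped wave


@pytest.fixture
def toy_panel():
    return pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "b", "c", "c", "c"],
            "time_years": [0.0, 2.0, 0.0, 2.0, 0.0, 2.0, 4.0],
            "observation": [
                "fit", "fit",
                "fit", "died",
                "vulnerable", "missing", "frail",
            ],
        }
    )


@pytest.fixture
def adjacent_generator():
    """A generator with only adjacent-state and death intensities."""
    return np.array(
        [
            [-0.33, 0.31, 0.00, 0.02],
            [0.20, -0.37, 0.15, 0.02],
            [0.00, 0.16, -0.31, 0.15],
            [0.00, 0.00, 0.00, 0.00],
        ]
    )
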