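"""Classification-tree engine for scoring the Clinical Frailty Scale.

A :class:`TreeDefinition` is a binary decision tree over the six items of an
:class:`~frailkit.items.ItemVector`; each leaf carries a CFS category (1-9).
The engine is generic: any tree over the six items can be supplied as a
JSON/YAML config, and the package ships a default operationalisation in
``frailkit/data/default_tree.json``.

Categories collapse onto the three analysis states used by the transition
model: CFS 1-3 are *fit*, CFS 4 is *vulnerable*, CFS 5+ is *frail*.

:class:`CFSTreeClassifier` wraps the engine as a scikit-learn estimator so
tree scoring composes with sklearn pipelines.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin

from .items import EFFORT_LEVELS, SELF_RATED_HEALTH_LEVELS, ItemVector

__all__ = [
    "ITEM_NAMES",
    "ItemDomain",
    "TreeDefinition",
    "ValidationReport",
    "classify",
    "collapse_state",
    "validate_tree",
    "load_default_tree",
    "CFSTreeClassifier",
]

ITEM_NAMES: tuple[str, ...] = (
    "badl_help_count",
    "iadl_help_count",
    "condition_count",
    "self_rated_health",
    "effort_frequency",
    "active_past_week",
)

_OPS = ("<", "<=", ">=", ">", "==", "in")

_ORDINAL_ORDER: dict[str, tuple[str, ...]] = {
    "self_rated_health": SELF_RATED_HEALTH_LEVELS,
    "effort_frequency": EFFORT_LEVELS,
}


@dataclass(frozen=True)
class ItemDomain:
    """Discretised item domain used for enumeration and uniform sampling.

    Count items are bounded (six BADL and six IADL items by default, 28
    conditions); ordinals and the activity flag take their declared levels.
    """

    badl_max: int = 6
    iadl_max: int = 6
    condition_max: int = 28

    def levels(self, item: str) -> Sequence:
        if item == "badl_help_count":
            return range(self.badl_max + 1)
        if item == "iadl_help_count":
            return range(self.iadl_max + 1)
        if item == "condition_count":
            return range(self.condition_max + 1)
        if item == "self_rated_health":
            return SELF_RATED_HEALTH_LEVELS
        if item == "effort_frequency":
            return EFFORT_LEVELS
        if item == "active_past_week":
            return (False, True)
        raise KeyError(item)

    def enumerate(self) -> Iterator[dict]:
        """Yield every item vector in the domain as a plain dict."""
        for combo in itertools.product(*(self.levels(n) for n in ITEM_NAMES)):
            yield dict(zip(ITEM_NAMES, combo))

    @property
    def size(self) -> int:
        n = 1
        for name in ITEM_NAMES:
            n *= len(self.levels(name))
        return n


def _item_value(items, name: str):
    if isinstance(items, Mapping):
        if name not in items:
            raise ValueError(f"item vector is missing item {name!r}")
        return items[name]
    return getattr(items, name)


def _ordinal_rank(item: str, value) -> int:
    order = _ORDINAL_ORDER[item]
    try:
        return order.index(value)
    except ValueError:
        raise ValueError(
            f"value {value!r} outside the declared domain of item {item!r}"
        ) from None


def _evaluate_split(node: Mapping, items) -> bool:
    item, op, ref = node["item"], node["op"], node["value"]
    value = _item_value(items, item)
    if item in _ORDINAL_ORDER:
        if op == "in":
            refs = {str(r) for r in ref}
            bad = refs - set(_ORDINAL_ORDER[item])
            if bad:
                raise ValueError(
                    f"split on {item!r} references unknown levels {sorted(bad)}"
                )
            # validates the observed value too
            _ordinal_rank(item, value)
            return value in refs
        lhs, rhs = _ordinal_rank(item, value), _ordinal_rank(item, ref)
    elif item == "active_past_week":
        lhs, rhs = bool(value), bool(ref)
        if op == "in":
            return lhs in {bool(r) for r in ref}
    else:
        if isinstance(value, (float, np.floating)) and float(value).is_integer():
            value = int(value)  # CSV round-trips integers as floats
        if not isinstance(value, (int, np.integer)) or isinstance(value, bool) or value < 0:
            raise ValueError(
                f"value {value!r} outside the declared domain of item {item!r}"
            )
        if op == "in":
            return value in set(ref)
        lhs, rhs = value, ref
    if op == "<":
        return lhs < rhs
    if op == "<=":
        return lhs <= rhs
    if op == ">=":
        return lhs >= rhs
    if op == ">":
        return lhs > rhs
    if op == "==":
        return lhs == rhs
    raise ValueError(f"unknown comparison operator {op!r}")


@dataclass
class TreeDefinition:
    """A decision tree over the six items with CFS-category leaves.

    ``root`` is a nested dict: internal nodes are
    ``{"item", "op", "value", "children": {"yes": ..., "no": ...}}`` and
    leaves are ``{"cfs": <int 1-9>}``.  The dict is kept verbatim so a file
    round-trips bit-exactly.
    """

    root: dict

    # --- IO -------------------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "TreeDefinition":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            return cls(yaml.safe_load(text))
        return cls(json.loads(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.root, sort_keys=False), encoding="utf-8")
        else:
            path.write_text(json.dumps(self.root, indent=1), encoding="utf-8")

    def fingerprint(self) -> str:
        return json.dumps(self.root, sort_keys=True)

    # --- scoring --------------------------------------------------------
    def classify(self, items) -> int:
        node = self.root
        while "cfs" not in node:
            branch = "yes" if _evaluate_split(node, items) else "no"
            node = node["children"][branch]
        return int(node["cfs"])

    # --- enumeration ----------------------------------------------------
    def preimage(self, domain: ItemDomain | None = None) -> dict[int, list[tuple]]:
        """Partition the discretised domain by assigned category.

        Returns ``{category: [item tuples in ITEM_NAMES order]}``; cached per
        domain on the instance.
        """
        domain = domain or ItemDomain()
        cache = self.__dict__.setdefault("_preimage_cache", {})
        key = (domain.badl_max, domain.iadl_max, domain.condition_max)
        if key not in cache:
            out: dict[int, list[tuple]] = {}
            for vec in domain.enumerate():
                out.setdefault(self.classify(vec), []).append(
                    tuple(vec[n] for n in ITEM_NAMES)
                )
            cache[key] = out
        return cache[key]


def classify(items, tree: TreeDefinition) -> int:
    """Score one item vector; deterministic, exactly one leaf reached."""
    return tree.classify(items)


def collapse_state(category: int) -> str:
    """Collapse a CFS category onto an analysis state.

    CFS 1-3 -> ``fit``; CFS 4 -> ``vulnerable``; CFS 5-9 -> ``frail``.
    """
    c = int(category)
    if not 1 <= c <= 9:
        raise ValueError(f"CFS category must be in 1..9, got {category!r}")
    if c <= 3:
        return "fit"
    if c == 4:
        return "vulnerable"
    return "frail"


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)
    reachable_categories: set[int] = field(default_factory=set)
    leaf_categories: set[int] = field(default_factory=set)

    @property
    def is_valid(self) -> bool:
        return not self.issues


def _walk_structure(node, report: ValidationReport, domain: ItemDomain, path: str) -> None:
    if not isinstance(node, Mapping):
        report.issues.append(f"{path}: node is not a mapping")
        return
    if "cfs" in node:
        cfs = node["cfs"]
        if not isinstance(cfs, int) or not 1 <= cfs <= 9:
            report.issues.append(f"{path}: leaf category {cfs!r} outside 1..9")
        else:
            report.leaf_categories.add(cfs)
        return
    item = node.get("item")
    if item not in ITEM_NAMES:
        report.issues.append(f"{path}: unknown item {item!r}")
        return
    op = node.get("op")
    if op not in _OPS:
        report.issues.append(f"{path}: unknown operator {op!r}")
        return
    value = node.get("value")
    if item in _ORDINAL_ORDER:
        refs = value if op == "in" else [value]
        for r in refs:
            if r not in _ORDINAL_ORDER[item]:
                report.issues.append(f"{path}: level {r!r} not a level of {item!r}")
    elif item != "active_past_week":
        refs = value if op == "in" else [value]
        lo, hi = 0, max(domain.levels(item))
        for r in refs:
            if not isinstance(r, (int, float)) or r < lo or r > hi:
                report.issues.append(
                    f"{path}: threshold {r!r} outside domain [0, {hi}] of {item!r}"
                )
    children = node.get("children")
    if not isinstance(children, Mapping) or set(children) != {"yes", "no"}:
        report.issues.append(f"{path}: internal node must have 'yes'/'no' children")
        return
    _walk_structure(children["yes"], report, domain, path + "/yes")
    _walk_structure(children["no"], report, domain, path + "/no")


def validate_tree(tree: TreeDefinition, domain: ItemDomain | None = None) -> ValidationReport:
    """Report structural problems, unreachable leaves and empty preimages.

    A valid tree yields an empty issue list.  Unreachable leaf categories
    (empty preimage under the domain bounds) are reported as issues since
    the simulator cannot invert them.
    """
    domain = domain or ItemDomain()
    report = ValidationReport()
    _walk_structure(tree.root, report, domain, path="root")
    if report.issues:
        return report
    reached = set(tree.preimage(domain))
    report.reachable_categories = reached
    empty = sorted(report.leaf_categories - reached)
    if empty:
        report.issues.append(
            f"categories with empty preimage under the domain bounds: {empty}"
        )
    return report


def load_default_tree() -> TreeDefinition:
    """Load the tree definition shipped with the package."""
    path = Path(__file__).parent / "data" / "default_tree.json"
    return TreeDefinition.from_file(path)


class CFSTreeClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator scoring CFS categories from the six items.

    Parameters
    ----------
    tree
        A :class:`TreeDefinition`, a nested node dict, a path to a
        JSON/YAML tree file, or ``None`` for the shipped default tree.
    domain
        :class:`ItemDomain` bounds used for validation; defaults apply.

    After :meth:`fit` the validated tree is available as ``tree_`` and the
    reachable categories as ``classes_``.
    """

    def __init__(self, tree=None, domain=None):
        self.tree = tree
        self.domain = domain

    def _resolve_tree(self) -> TreeDefinition:
        if self.tree is None:
            return load_default_tree()
        if isinstance(self.tree, TreeDefinition):
            return self.tree
        if isinstance(self.tree, (str, Path)):
            return TreeDefinition.from_file(self.tree)
        return TreeDefinition(self.tree)

    def fit(self, X=None, y=None) -> "CFSTreeClassifier":
        tree = self._resolve_tree()
        report = validate_tree(tree, self.domain)
        if report.issues:
            raise ValueError("invalid tree definition: " + "; ".join(report.issues))
        self.tree_ = tree
        self.report_ = report
        self.classes_ = np.array(sorted(report.reachable_categories))
        return self

    def _iter_records(self, X) -> Iterable:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in ITEM_NAMES if c not in X.columns]
            if missing:
                raise ValueError(f"item columns missing from input: {missing}")
            return (row._asdict() for row in X[list(ITEM_NAMES)].itertuples(index=False))
        return X

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "tree_"):
            self.fit()
        return np.array([self.tree_.classify(rec) for rec in self._iter_records(X)])

    def predict_state(self, X) -> np.ndarray:
        """Predict collapsed analysis states (fit / vulnerable / frail)."""
        return np.array([collapse_state(c) for c in self.predict(X)], dtype=object)
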