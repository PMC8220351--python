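"""Derivation of the six classification-tree items from raw questionnaire fields.

The Clinical Frailty Scale (CFS) classification-tree approach scores frailty
from six questionnaire-derived items:

* number of basic activities of daily living (BADL) requiring help,
* number of instrumental activities of daily living (IADL) requiring help,
* number of chronic and cardiovascular conditions (out of 28),
* self-rated health (excellent .. poor),
* how often in the past week everything felt like an effort (a CES-D item),
* whether the respondent did moderate or vigorous activity on at least one
  day in the past week (IPAQ-SF).

This module turns a raw questionnaire record (boolean condition and help
flags plus the three ordinal/boolean items) into a validated
:class:`ItemVector`.  No imputation is performed: a missing required field is
an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "CONDITION_NAMES",
    "SELF_RATED_HEALTH_LEVELS",
    "EFFORT_LEVELS",
    "ItemVector",
    "derive_item_vector",
    "canonical_level",
]

#: The 28 cardiovascular and chronic conditions counted for the tree, in the
#: questionnaire order.
CONDITION_NAMES: tuple[str, ...] = (
    "hypertension",
    "angina",
    "heart_attack",
    "congestive_heart_failure",
    "diabetes",
    "stroke",
    "transient_ischaemic_attack",
    "high_cholesterol",
    "heart_murmur",
    "abnormal_heart_rhythm",
    "other_heart_trouble",
    "chronic_lung_disease",
    "asthma",
    "arthritis",
    "osteoporosis",
    "cancer",
    "parkinsons_disease",
    "emotional_or_psychiatric_problems",
    "alcohol_or_substance_abuse",
    "alzheimers_disease",
    "dementia",
    "serious_memory_impairment",
    "stomach_ulcers",
    "varicose_ulcers",
    "cirrhosis",
    "cataracts",
    "glaucoma",
    "macular_degeneration",
)

#: Canonical ordinal levels, worst last.
SELF_RATED_HEALTH_LEVELS: tuple[str, ...] = (
    "excellent",
    "very good",
    "good",
    "fair",
    "poor",
)

#: Canonical levels for the "everything was an effort" frequency item.
EFFORT_LEVELS: tuple[str, ...] = ("rarely", "some", "occasional", "all")

# Common questionnaire-export phrasings mapped onto the canonical levels.
_EFFORT_ALIASES: dict[str, str] = {
    "rarely": "rarely",
    "rarely or none of the time": "rarely",
    "none": "rarely",
    "rarely/none": "rarely",
    "some": "some",
    "some or a little of the time": "some",
    "a little": "some",
    "some/little": "some",
    "occasional": "occasional",
    "occasionally": "occasional",
    "occasionally or a moderate amount of time": "occasional",
    "moderate": "occasional",
    "occasionally/moderate": "occasional",
    "all": "all",
    "all of the time": "all",
}

_SRH_ALIASES: dict[str, str] = {lvl: lvl for lvl in SELF_RATED_HEALTH_LEVELS}
_SRH_ALIASES["verygood"] = "very good"
_SRH_ALIASES["very_good"] = "very good"


def canonical_level(field: str, value: str) -> str:
    """Map a raw ordinal label to its canonical level (case-insensitive).

    Raises ``ValueError`` for labels outside the declared domain.
    """
    key = str(value).strip().lower()
    aliases = _SRH_ALIASES if field == "self_rated_health" else _EFFORT_ALIASES
    if key not in aliases:
        raise ValueError(f"unknown level {value!r} for item {field!r}")
    return aliases[key]


@dataclass(frozen=True)
class ItemVector:
    """The six classification-tree inputs for one participant-wave."""

    badl_help_count: int
    iadl_help_count: int
    condition_count: int
    self_rated_health: str
    effort_frequency: str
    active_past_week: bool

    def __post_init__(self) -> None:
        for f in ("badl_help_count", "iadl_help_count", "condition_count"):
            v = getattr(self, f)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{f} must be a non-negative integer, got {v!r}")
        if self.condition_count > len(CONDITION_NAMES):
            raise ValueError(
                f"condition_count must be <= {len(CONDITION_NAMES)}, "
                f"got {self.condition_count}"
            )
        if self.self_rated_health not in SELF_RATED_HEALTH_LEVELS:
            raise ValueError(
                f"self_rated_health must be one of {SELF_RATED_HEALTH_LEVELS}, "
                f"got {self.self_rated_health!r}"
            )
        if self.effort_frequency not in EFFORT_LEVELS:
            raise ValueError(
                f"effort_frequency must be one of {EFFORT_LEVELS}, "
                f"got {self.effort_frequency!r}"
            )
        if not isinstance(self.active_past_week, bool):
            raise ValueError(
                f"active_past_week must be boolean, got {self.active_past_week!r}"
            )


def _count_flags(raw: Mapping, key: str, expected: int | None = None) -> int:
    if key not in raw:
        raise ValueError(f"missing required field {key!r}")
    flags = raw[key]
    if isinstance(flags, Mapping):
        if expected is not None:
            missing = [n for n in CONDITION_NAMES if n not in flags]
            if missing:
                raise ValueError(f"missing condition flags: {missing}")
            values: Sequence = [flags[n] for n in CONDITION_NAMES]
        else:
            values = list(flags.values())
    else:
        values = list(flags)
        if expected is not None and len(values) != expected:
            raise ValueError(
                f"{key!r} must supply {expected} flags, got {len(values)}"
            )
    return int(sum(bool(v) for v in values))


def derive_item_vector(raw: Mapping) -> ItemVector:
    """Derive the six tree items from a raw questionnaire record.

    Parameters
    ----------
    raw
        Mapping with keys ``conditions`` (28 boolean flags, sequence in the
        questionnaire order or a dict keyed by :data:`CONDITION_NAMES`),
        ``badl_help`` and ``iadl_help`` (boolean flag sequences),
        ``self_rated_health``, ``effort_frequency`` and ``active_past_week``.

    Counts are sums of true flags; ordinal labels are matched
    case-insensitively against the canonical levels.  Missing required
    fields raise ``ValueError`` — no imputation.
    """
    condition_count = _count_flags(raw, "conditions", expected=len(CONDITION_NAMES))
    badl = _count_flags(raw, "badl_help")
    iadl = _count_flags(raw, "iadl_help")
    for key in ("self_rated_health", "effort_frequency", "active_past_week"):
        if key not in raw or raw[key] is None:
            raise ValueError(f"missing required field {key!r}")
    return ItemVector(
        badl_help_count=badl,
        iadl_help_count=iadl,
        condition_count=condition_count,
        self_rated_health=canonical_level("self_rated_health", raw["self_rated_health"]),
        effort_frequency=canonical_level("effort_frequency", raw["effort_frequency"]),
        active_past_week=bool(raw["active_past_week"]),
    )
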