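"""Synthetic longitudinal frailty cohorts with mortality and attrition.

The generator emulates the panel structure the transition analysis assumes:
subjects aged 65+ observed at (nominally biennial) waves, frailty states
evolving between waves as a continuous-time Markov chain with an absorbing
death state, wave-on-wave missing-at-random attrition, CFS categories and
item vectors consistent with the configured classification tree, survey
attrition weights with mean 1, and category-conditional health and
social-care utilisation variables.

States evolve by one multinomial draw per interval from the generator's
interval transition matrix exp(Q * spacing) — exactly the law the
interval-censored estimator assumes.  Item vectors are sampled uniformly
from the classification tree's preimage of the assigned category, so
scoring a generated vector always returns the generating category.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import presets
from .items import ItemVector
from .msm import DIED, STATES, transition_probability, validate_generator
from .tree import ITEM_NAMES, ItemDomain, TreeDefinition, collapse_state, load_default_tree

__all__ = [
    "CareParams",
    "UtilisationParams",
    "SimConfig",
    "simulate_cohort",
    "generate_items",
    "to_model_panel",
    "write_panel",
    "read_panel",
]

_STATE_CATEGORY_SLICES = {0: slice(0, 3), 1: slice(3, 4), 2: slice(4, 7)}


@dataclass
class CareParams:
    """Category-conditional care receipt and intensity for one provider type.

    ``receipt_prob`` is the probability of receiving any care of this type;
    conditional on receipt, hours/day are gamma with the given mean (shape
    ``hours_shape``) and days/month are binomial(31, mean/31), so the days
    mean is exact and the support stays in [0, 31].
    """

    receipt_prob: np.ndarray
    hours_per_day_mean: np.ndarray
    days_per_month_mean: np.ndarray
    hours_shape: float = 2.0

    def monthly_hours_mean(self) -> np.ndarray:
        """Implied unconditional mean monthly hours per category."""
        return self.receipt_prob * self.hours_per_day_mean * self.days_per_month_mean


@dataclass
class UtilisationParams:
    """Category-conditional distributions of the utilisation variables.

    Count variables are Poisson by default; a dispersion value ``k`` makes
    them negative binomial with that size parameter (same mean,
    overdispersed).  ``service_probs`` is a (13 services x 7 categories)
    Bernoulli probability matrix.
    """

    count_means: dict[str, np.ndarray]
    count_dispersion: dict[str, float | None]
    service_probs: np.ndarray
    care: dict[str, CareParams]

    def validate(self) -> None:
        for name, m in self.count_means.items():
            if np.asarray(m).shape != (7,) or (np.asarray(m) < 0).any():
                raise ValueError(f"utilisation_params.count_means[{name!r}] must be 7 non-negative means")
        if self.service_probs.shape != (len(presets.SERVICE_NAMES), 7):
            raise ValueError("utilisation_params.service_probs must be 13x7")
        if ((self.service_probs < 0) | (self.service_probs > 1)).any():
            raise ValueError("utilisation_params.service_probs must be probabilities")
        for name, cp in self.care.items():
            for f in ("receipt_prob", "hours_per_day_mean", "days_per_month_mean"):
                if np.asarray(getattr(cp, f)).shape != (7,):
                    raise ValueError(f"utilisation_params.care[{name!r}].{f} must have 7 entries")
            if ((cp.receipt_prob < 0) | (cp.receipt_prob > 1)).any():
                raise ValueError(f"utilisation_params.care[{name!r}].receipt_prob must be probabilities")
            if ((cp.days_per_month_mean < 0) | (cp.days_per_month_mean > 31)).any():
                raise ValueError(f"utilisation_params.care[{name!r}].days_per_month_mean must be in [0, 31]")


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    Defaults reproduce the published study conditions: five biennial waves,
    CFS categories drawn from the published final-wave prevalence, state
    dynamics from the generator calibrated to the published 2-year matrix,
    5% per-wave missingness, and lognormal mean-1 attrition weights.
    """

    n_subjects: int
    n_waves: int = 5
    wave_spacing: float = 2.0
    wave_offsets: np.ndarray | None = None
    baseline_category_probs: np.ndarray = None  # type: ignore[assignment]
    baseline_state_probs: np.ndarray | None = None
    generator: np.ndarray = None  # type: ignore[assignment]
    missing_hazard: float = 0.05
    utilisation_params: UtilisationParams = None  # type: ignore[assignment]
    weight_model: Mapping = field(default_factory=lambda: {"dist": "lognormal", "sigma": 0.5})
    tree: TreeDefinition | None = None
    domain: ItemDomain = field(default_factory=ItemDomain)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_category_probs is None:
            self.baseline_category_probs = presets.category_probs()
        if self.generator is None:
            self.generator = presets.reference_generator()
        if self.utilisation_params is None:
            self.utilisation_params = presets.default_utilisation_params()
        if self.tree is None:
            self.tree = load_default_tree()

    def wave_times(self) -> np.ndarray:
        if self.wave_offsets is not None:
            t = np.asarray(self.wave_offsets, dtype=float)
            if len(t) != self.n_waves or (np.diff(t) <= 0).any():
                raise ValueError("wave_offsets must be n_waves strictly increasing times")
            return t
        return np.arange(self.n_waves) * float(self.wave_spacing)

    def state_probs(self) -> np.ndarray:
        p = np.asarray(self.baseline_category_probs, dtype=float)
        return np.array([p[sl].sum() for sl in _STATE_CATEGORY_SLICES.values()])

    def validate(self) -> None:
        if not isinstance(self.n_subjects, int) or self.n_subjects <= 0:
            raise ValueError("n_subjects must be a positive integer")
        if not isinstance(self.n_waves, int) or self.n_waves <= 0:
            raise ValueError("n_waves must be a positive integer")
        if self.wave_spacing <= 0:
            raise ValueError("wave_spacing must be positive")
        p = np.asarray(self.baseline_category_probs, dtype=float)
        if p.shape != (7,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("baseline_category_probs must be 7 non-negative probabilities summing to 1")
        if self.baseline_state_probs is not None:
            s = np.asarray(self.baseline_state_probs, dtype=float)
            if s.shape != (3,) or (s < 0).any() or abs(s.sum() - 1.0) > 1e-12:
                raise ValueError("baseline_state_probs must be 3 non-negative probabilities summing to 1")
            if np.abs(s - self.state_probs()).max() > 1e-12:
                raise ValueError(
                    "baseline_state_probs inconsistent with the collapse of baseline_category_probs"
                )
        try:
            validate_generator(self.generator)
        except ValueError as e:
            raise ValueError(f"generator: {e}") from None
        if not 0 <= self.missing_hazard < 1:
            raise ValueError("missing_hazard must be in [0, 1)")
        self.utilisation_params.validate()
        if self.weight_model.get("dist") not in ("lognormal", "constant"):
            raise ValueError("weight_model.dist must be 'lognormal' or 'constant'")
        self.wave_times()


def generate_items(category: int, tree: TreeDefinition, rng, domain: ItemDomain | None = None) -> ItemVector:
    """Sample an item vector uniformly from the tree's preimage of a category.

    Classifying the result under the same tree always returns ``category``;
    an unreachable category is an error.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    domain = domain or ItemDomain()
    pre = tree.preimage(domain)
    if category not in pre or not pre[category]:
        raise ValueError(
            f"CFS category {category} has an empty preimage under this tree/domain"
        )
    vals = pre[category][rng.integers(len(pre[category]))]
    return ItemVector(**dict(zip(ITEM_NAMES, vals)))


def _draw_categorical(rng, probs: np.ndarray, n: int) -> np.ndarray:
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(n), side="right")


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate one long-format cohort panel; deterministic given the seed.

    One row per subject per wave with ``status`` observed / missing / died
    (death is ascertained at every wave, so it overrides missingness and is
    carried forward).  Item vectors, categories and utilisation variables
    are present only on observed rows.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, w = config.n_subjects, config.n_waves
    times = config.wave_times()
    cat_probs = np.asarray(config.baseline_category_probs, dtype=float)

    # --- state dynamics ------------------------------------------------
    state = np.empty((n, w), dtype=int)
    cat0 = _draw_categorical(rng, cat_probs, n)  # 0-based CFS index
    state[:, 0] = [0 if c < 3 else (1 if c == 3 else 2) for c in cat0]
    for k in range(1, w):
        P = transition_probability(config.generator, times[k] - times[k - 1])
        cum = np.cumsum(P, axis=1)
        u = rng.random(n)
        state[:, k] = (u[:, None] > cum[state[:, k - 1]]).sum(axis=1)

    # --- missingness (MAR, never at baseline; death overrides) ---------
    miss = rng.random((n, w)) < config.missing_hazard
    miss[:, 0] = False

    # --- categories conditional on state -------------------------------
    category = np.zeros((n, w), dtype=int)
    category[:, 0] = cat0 + 1
    cond = {
        s: cat_probs[sl] / cat_probs[sl].sum() if cat_probs[sl].sum() > 0 else None
        for s, sl in _STATE_CATEGORY_SLICES.items()
    }
    for k in range(1, w):
        for s, sl in _STATE_CATEGORY_SLICES.items():
            rows = np.flatnonzero(state[:, k] == s)
            if rows.size == 0:
                continue
            if cond[s] is None:
                raise ValueError(
                    f"state {STATES[s]!r} reachable but has zero baseline category mass"
                )
            category[rows, k] = sl.start + 1 + _draw_categorical(rng, cond[s], rows.size)

    died = state == DIED
    observed = ~died & ~miss
    status = np.where(died, "died", np.where(miss, "missing", "observed"))

    # --- weights (subject-level, mean 1) -------------------------------
    wm = dict(config.weight_model)
    if wm.get("dist") == "constant":
        weight = np.ones(n)
    else:
        sigma = float(wm.get("sigma", 0.5))
        weight = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)

    # --- assemble frame -------------------------------------------------
    rec = {
        "subject_id": np.repeat(np.arange(n), w),
        "wave_index": np.tile(np.arange(w), n),
        "time_years": np.tile(times, n),
        "status": status.reshape(-1),
        "weight": np.repeat(weight, w),
    }
    df = pd.DataFrame(rec)
    obs_flat = observed.reshape(-1)
    cat_flat = np.where(obs_flat, category.reshape(-1), 0)
    df["cfs_category"] = pd.array(
        np.where(obs_flat, cat_flat, np.nan), dtype="Int64"
    )
    state_lbl = np.array(STATES, dtype=object)[state.reshape(-1)]
    state_lbl[miss.reshape(-1) & ~died.reshape(-1)] = None
    df["state"] = state_lbl

    # --- item vectors: uniform draw from the tree preimage --------------
    pre = config.tree.preimage(config.domain)
    item_cols: dict[str, np.ndarray] = {
        name: np.full(n * w, np.nan, dtype=object) for name in ITEM_NAMES
    }
    for c in sorted(np.unique(cat_flat[obs_flat])):
        if c == 0:
            continue
        if c not in pre or not pre[c]:
            raise ValueError(
                f"CFS category {c} has an empty preimage under this tree/domain"
            )
        rows = np.flatnonzero(obs_flat & (cat_flat == c))
        choices = rng.integers(len(pre[c]), size=rows.size)
        vecs = pre[c]
        for j, name in enumerate(ITEM_NAMES):
            item_cols[name][rows] = [vecs[i][j] for i in choices]
    for name in ITEM_NAMES:
        df[name] = item_cols[name]

    # --- utilisation ----------------------------------------------------
    up = config.utilisation_params
    cat_idx = cat_flat - 1  # -1 where unobserved
    for var in presets.COUNT_VARIABLES:
        means = up.count_means[var]
        out = np.full(n * w, np.nan)
        mu = np.where(obs_flat, means[np.clip(cat_idx, 0, 6)], 0.0)
        disp = up.count_dispersion.get(var)
        if disp is None:
            draws = rng.poisson(mu)
        else:
            # negative binomial with size k and mean mu
            p = disp / (disp + np.maximum(mu, 1e-12))
            draws = rng.negative_binomial(disp, p)
        out[obs_flat] = draws[obs_flat]
        df[var] = pd.array(out, dtype="Int64")
    for si, sname in enumerate(presets.SERVICE_NAMES):
        p = np.where(obs_flat, up.service_probs[si, np.clip(cat_idx, 0, 6)], 0.0)
        out = np.full(n * w, np.nan)
        out[obs_flat] = (rng.random(n * w) < p)[obs_flat]
        df[f"svc_{sname}"] = pd.array(out, dtype="Int64")
    for cname, cp in up.care.items():
        receipt = np.where(obs_flat, cp.receipt_prob[np.clip(cat_idx, 0, 6)], 0.0)
        got = rng.random(n * w) < receipt
        h_mean = np.maximum(cp.hours_per_day_mean[np.clip(cat_idx, 0, 6)], 1e-12)
        hours = rng.gamma(cp.hours_shape, h_mean / cp.hours_shape)
        days = rng.binomial(31, cp.days_per_month_mean[np.clip(cat_idx, 0, 6)] / 31.0)
        h = np.where(got, hours, 0.0)
        d = np.where(got, days, 0.0)
        hcol = np.full(n * w, np.nan)
        dcol = np.full(n * w, np.nan)
        hcol[obs_flat] = h[obs_flat]
        dcol[obs_flat] = d[obs_flat]
        df[f"{cname}_hours_day"] = hcol
        df[f"{cname}_days_month"] = dcol
    return df


def to_model_panel(cohort: pd.DataFrame) -> pd.DataFrame:
    """Convert a cohort panel to the estimator's (subject, time, observation) form.

    Observed rows map to their collapsed state; missing rows to ``missing``;
    only the first died row is kept (death is a single event, carried-forward
    rows are bookkeeping for the flow tables).
    """
    df = cohort.sort_values(["subject_id", "wave_index"])
    obs = np.where(
        df["status"] == "observed",
        [collapse_state(c) if pd.notna(c) else "missing" for c in df["cfs_category"]],
        df["status"],
    )
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"].to_numpy(),
            "time_years": df["time_years"].to_numpy(),
            "observation": obs,
        }
    )
    dead = out["observation"] == "died"
    carried = dead & dead.groupby(out["subject_id"]).shift(fill_value=False)
    return out[~carried].reset_index(drop=True)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a panel as UTF-8 CSV with empty cells for missing values."""
    panel.to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("cfs_category", *presets.COUNT_VARIABLES):
        if col in df.columns:
            df[col] = pd.array(df[col], dtype="Int64")
    for col in df.columns:
        if col.startswith("svc_"):
            df[col] = pd.array(df[col], dtype="Int64")
    return df
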