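"""Continuous-time multi-state Markov model for interval-censored frailty panels.

The model has four states in fixed order — ``fit``, ``vulnerable``, ``frail``
and absorbing ``died`` — and is governed by a transition-intensity
(generator) matrix Q: off-diagonal entries are instantaneous transition
rates, rows sum to zero, and the interval law is the matrix exponential
P(t) = exp(Qt).

Panel observations are interval-censored: states are seen only at wave
times, and a death is known only to have happened before the wave at which
it was ascertained.  The likelihood of a subject's record is the product of
interval terms P(t2-t1)[a, b] over consecutive non-missing observations;
a ``died`` observation contributes the entry [a, died], which already sums
over all paths into death within the interval.  Missing waves are skipped
via the Markov property; subjects are not dropped.

:class:`MultiStateMarkov` is a scikit-learn style estimator maximising this
likelihood over log-intensities (so any optimiser iterate is a valid
generator).  Confidence intervals for the fitted transition-probability
matrix come from a seeded parametric bootstrap on the observed wave grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm, logm
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = [
    "STATES",
    "DIED",
    "structure_mask",
    "validate_generator",
    "transition_probability",
    "nearest_generator",
    "NearestGeneratorResult",
    "log_likelihood",
    "MultiStateMarkov",
    "FitResult",
    "fit_model",
    "bootstrap_ci",
]

#: Fixed state order of every matrix in this module.
STATES: tuple[str, ...] = ("fit", "vulnerable", "frail", "died")
N_STATES = 4
DIED = 3
_STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}


def structure_mask(kind: str = "adjacent") -> np.ndarray:
    """Boolean mask of allowed instantaneous transitions (off-diagonal).

    ``"adjacent"`` allows moves between neighbouring severity states
    (fit<->vulnerable, vulnerable<->frail) plus death from every transient
    state; direct fit<->frail jumps are excluded (they remain reachable over
    an interval via two jumps).  ``"full"`` allows every transient
    off-diagonal move.
    """
    mask = np.zeros((N_STATES, N_STATES), dtype=bool)
    if kind == "adjacent":
        for a, b in [(0, 1), (1, 0), (1, 2), (2, 1)]:
            mask[a, b] = True
    elif kind == "full":
        for a in range(DIED):
            for b in range(DIED):
                if a != b:
                    mask[a, b] = True
    else:
        raise ValueError(f"unknown structure {kind!r}")
    mask[:DIED, DIED] = True
    return mask


def validate_generator(Q: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (N_STATES, N_STATES):
        raise ValueError(f"generator must be {N_STATES}x{N_STATES}, got {Q.shape}")
    off = Q[~np.eye(N_STATES, dtype=bool)]
    if (off < -tol).any():
        raise ValueError("generator has negative off-diagonal intensities")
    if np.abs(Q.sum(axis=1)).max() > 1e-6:
        raise ValueError("generator rows must sum to 0")
    if np.abs(Q[DIED]).max() > tol:
        raise ValueError("died row of the generator must be 0 (absorbing)")
    return Q


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """Interval transition-probability matrix P(t) = exp(Qt).

    Tiny negative round-off entries are clipped to 0 and rows renormalised;
    the result is row-stochastic with an absorbing died row.
    """
    if t < 0:
        raise ValueError(f"elapsed time must be non-negative, got {t}")
    Q = validate_generator(Q)
    P = expm(Q * float(t))
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


@dataclass(frozen=True)
class NearestGeneratorResult:
    Q: np.ndarray
    max_abs_error: float


def nearest_generator(P: np.ndarray, t: float) -> NearestGeneratorResult:
    """Calibrate a valid generator to an interval matrix P observed at lag t.

    Takes the principal matrix logarithm of P divided by t, clips negative
    off-diagonal entries to zero, rebalances the diagonal and zeroes the
    absorbing row; returns the generator together with the maximum absolute
    entry error of exp(Q*t) against the input.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (N_STATES, N_STATES):
        raise ValueError(f"matrix must be {N_STATES}x{N_STATES}, got {P.shape}")
    if (P < -1e-12).any() or np.abs(P.sum(axis=1) - 1.0).max() > 1e-8:
        raise ValueError("input must be row-stochastic (renormalise rows first)")
    if t <= 0:
        raise ValueError(f"lag must be positive, got {t}")
    L = logm(P)
    if np.abs(L.imag).max() > 1e-8:
        raise ValueError("matrix logarithm is not real; no nearby generator")
    Q = L.real / t
    np.fill_diagonal(Q, 0.0)
    Q[Q < 0] = 0.0
    Q[DIED, :] = 0.0
    np.fill_diagonal(Q, -Q.sum(axis=1))
    err = float(np.abs(expm(Q * t) - P).max())
    return NearestGeneratorResult(Q=Q, max_abs_error=err)


# ---------------------------------------------------------------------------
# panel handling


def _canon_panel(panel: pd.DataFrame) -> pd.DataFrame:
    cols = {c.lower(): c for c in panel.columns}
    sid = cols.get("subject_id")
    time = cols.get("time_years") or cols.get("time")
    obs = cols.get("observation") or cols.get("state")
    if sid is None or time is None or obs is None:
        raise ValueError(
            "panel must have columns subject_id, time_years (or time) and "
            "observation (or state)"
        )
    df = panel[[sid, time, obs]].copy()
    df.columns = ["subject_id", "time", "observation"]
    return df


def aggregate_intervals(panel: pd.DataFrame) -> dict[tuple[float, int, int], int]:
    """Collapse a panel into counts of (interval length, from, to) terms.

    Missing observations are skipped (Markov property); a ``died``
    observation terminates the subject's record.  The panel is validated:
    times strictly increasing within subject, nothing after a death.
    """
    df = _canon_panel(panel)
    counts: dict[tuple[float, int, int], int] = {}
    for sid, g in df.groupby("subject_id", sort=False):
        times = g["time"].to_numpy(dtype=float)
        if (np.diff(times) <= 0).any():
            raise ValueError(f"times not strictly increasing for subject {sid!r}")
        obs = list(g["observation"])
        prev_state: int | None = None
        prev_time = 0.0
        for tt, ob in zip(times, obs):
            if prev_state is not None and STATES[prev_state] == "died":
                raise ValueError(f"observation after death for subject {sid!r}")
            if ob == "missing" or (isinstance(ob, float) and np.isnan(ob)):
                continue
            if ob not in _STATE_INDEX:
                raise ValueError(f"unknown observation {ob!r} for subject {sid!r}")
            cur = _STATE_INDEX[ob]
            if prev_state is not None:
                key = (round(tt - prev_time, 9), prev_state, cur)
                counts[key] = counts.get(key, 0) + 1
            prev_state, prev_time = cur, tt
    return counts


def _counts_arrays(counts: Mapping[tuple[float, int, int], int]):
    dts = sorted({k[0] for k in counts})
    dt_index = {d: i for i, d in enumerate(dts)}
    keys = list(counts)
    idx = np.array([[dt_index[d], a, b] for d, a, b in keys], dtype=int)
    n = np.array([counts[k] for k in keys], dtype=float)
    return np.array(dts), idx, n


def _loglik_from_counts(Q: np.ndarray, dts, idx, n) -> float:
    ll = 0.0
    for i, dt in enumerate(dts):
        P = expm(Q * dt)
        sel = idx[:, 0] == i
        p = P[idx[sel, 1], idx[sel, 2]]
        if (p <= 0).any():
            return -np.inf
        ll += float(n[sel] @ np.log(p))
    return ll


def log_likelihood(Q: np.ndarray, panel: pd.DataFrame) -> float:
    """Interval-censored panel log-likelihood of generator Q.

    Empty panel (no consecutive observation pairs) gives 0.  A transition
    observed with zero probability under structural zeros of exp(Qt) yields
    ``-inf`` with a diagnostic warning.
    """
    Q = validate_generator(Q)
    counts = aggregate_intervals(panel)
    if not counts:
        return 0.0
    dts, idx, n = _counts_arrays(counts)
    ll = _loglik_from_counts(Q, dts, idx, n)
    if not np.isfinite(ll):
        bad = []
        for (dt, a, b), c in counts.items():
            if expm(Q * dt)[a, b] <= 0:
                bad.append((dt, STATES[a], STATES[b], c))
        warnings.warn(
            f"observed transitions have zero probability under Q: {bad}",
            RuntimeWarning,
            stacklevel=2,
        )
    return ll


# ---------------------------------------------------------------------------
# estimation


def _crude_init(counts, mask: np.ndarray) -> np.ndarray:
    """Crude empirical rates: observed a->b interval moves / person-time in a."""
    trans = np.zeros((N_STATES, N_STATES))
    at_risk = np.zeros(N_STATES)
    for (dt, a, b), c in counts.items():
        at_risk[a] += dt * c
        if a != b:
            trans[a, b] += c
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(at_risk[:, None] > 0, trans / np.maximum(at_risk[:, None], 1e-12), 0.0)
    q0 = np.clip(rates, 0.02, 2.0)
    q0[~mask] = 0.0
    return q0


def _assemble_Q(theta: np.ndarray, mask: np.ndarray) -> np.ndarray:
    Q = np.zeros((N_STATES, N_STATES))
    Q[mask] = np.exp(theta)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _negll_and_grad(theta, mask, dts, idx, n):
    """Negative log-likelihood and its gradient in log-intensities.

    The gradient uses the Frechet derivative of the matrix exponential,
    evaluated for all free intensities at once through the block identity
    expm([[A, D], [0, A]]) = [[e^A, L(A, D)], [0, e^A]].
    """
    Q = _assemble_Q(theta, mask)
    rows, cols = np.where(mask)
    m = rows.size
    ll = 0.0
    grad = np.zeros(m)
    for i, dt in enumerate(dts):
        sel = idx[:, 0] == i
        a, b, w = idx[sel, 1], idx[sel, 2], n[sel]
        M = np.zeros((m, 2 * N_STATES, 2 * N_STATES))
        M[:, :N_STATES, :N_STATES] = Q * dt
        M[:, N_STATES:, N_STATES:] = Q * dt
        for k in range(m):
            r, c = rows[k], cols[k]
            # dQ/dtheta_k = q_rc (E_rc - E_rr)
            M[k, r, N_STATES + c] = Q[r, c] * dt
            M[k, r, N_STATES + r] -= Q[r, c] * dt
        E = expm(M)
        P = E[0, :N_STATES, :N_STATES]
        dP = E[:, :N_STATES, N_STATES:]
        p = P[a, b]
        if (p <= 0).any() or not np.all(np.isfinite(p)):
            return 1e12, np.zeros(m)
        ll += float(w @ np.log(p))
        grad += dP[:, a, b] @ (w / p)
    return -ll, -grad


class MultiStateMarkov(BaseEstimator):
    """Maximum-likelihood multi-state Markov model on interval-censored panels.

    Parameters
    ----------
    structure : {"adjacent", "full"} or boolean (4, 4) array
        Mask of allowed instantaneous transitions; see :func:`structure_mask`.
    t_report : float
        Lag (years) at which the fitted transition-probability matrix
        ``P_`` is reported; 2.0 matches a biennial wave design.
    init : array or None
        Starting generator; ``None`` uses crude empirical rates.
    gtol, maxiter
        Quasi-Newton stopping controls (projected-gradient norm, iterations).

    Fitted attributes: ``Q_`` (generator), ``P_`` (transition matrix at
    ``t_report``), ``log_likelihood_``, ``converged_``, ``n_iter_``,
    ``mask_``, ``flagged_intensities_`` (allowed moves never observed
    directly in the data), and after :meth:`bootstrap_ci` the per-entry
    ``ci_`` bounds for ``P_``.
    """

    def __init__(self, structure="adjacent", t_report=2.0, init=None,
                 gtol=1e-8, maxiter=500):
        self.structure = structure
        self.t_report = t_report
        self.init = init
        self.gtol = gtol
        self.maxiter = maxiter

    # -- internals -------------------------------------------------------
    def _mask(self) -> np.ndarray:
        if isinstance(self.structure, str):
            return structure_mask(self.structure)
        mask = np.asarray(self.structure, dtype=bool)
        if mask.shape != (N_STATES, N_STATES):
            raise ValueError("structure mask must be 4x4 boolean")
        if mask[DIED].any() or mask.diagonal().any():
            raise ValueError("structure mask: died row and diagonal must be False")
        return mask

    def _fit_counts(self, counts):
        mask = self._mask()
        if not counts:
            raise ValueError("panel contains no observation intervals")
        dts, idx, n = _counts_arrays(counts)
        if self.init is not None:
            q0 = np.asarray(self.init, dtype=float).copy()
            q0[~mask] = 0.0
            q0 = np.clip(q0, 0.0, None)
        else:
            q0 = _crude_init(counts, mask)
        theta0 = np.log(np.maximum(q0[mask], 1e-4))

# log-intensity bounds keep rates in [6e-6, 20]/year: wide enough for
        # any biennial panel, tight enough to keep expm well-conditioned
        res = minimize(
            _negll_and_grad,
            theta0,
            args=(mask, dts, idx, n),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-12.0, 3.0)] * int(mask.sum()),
            options={"gtol": self.gtol, "maxiter": self.maxiter},
        )
        Q = _assemble_Q(res.x, mask)
        return Q, -float(res.fun), bool(res.success), int(res.nit), mask

    # -- API -------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "MultiStateMarkov":
        counts = aggregate_intervals(X)
        Q, ll, ok, nit, mask = self._fit_counts(counts)
        observed = np.zeros((N_STATES, N_STATES), dtype=bool)
        for (_, a, b) in counts:
            observed[a, b] = True
        self.flagged_intensities_ = [
            (STATES[a], STATES[b])
            for a in range(N_STATES)
            for b in range(N_STATES)
            if mask[a, b] and not observed[a, b]
        ]
        self.mask_ = mask
        self.Q_ = Q
        self.log_likelihood_ = ll
        self.converged_ = ok
        self.n_iter_ = nit
        self.P_ = transition_probability(Q, self.t_report)
        self._counts_ = counts
        if not ok:
            warnings.warn("optimiser did not report convergence", RuntimeWarning)
        return self

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Panel log-likelihood of the fitted generator on X."""
        return log_likelihood(self.Q_, X)

    # -- bootstrap -------------------------------------------------------
    def bootstrap_ci(self, X: pd.DataFrame, B: int = 500, seed: int | None = None,
                     max_dropped_frac: float = 0.2):
        """Parametric-bootstrap percentile CIs for the entries of ``P_``.

        Simulates ``B`` panels from the fitted generator on each subject's
        observed wave grid (preserving the missingness pattern), refits each,
        and returns (lower, upper) 4x4 arrays of 2.5/97.5 percentiles.
        Non-convergent replicates are dropped; more than
        ``max_dropped_frac`` dropped is an error.
        """
        if B < 2:
            raise ValueError("B must be >= 2")
        if not hasattr(self, "Q_"):
            raise ValueError("fit before bootstrap_ci")
        df = _canon_panel(X)
        grids: list[np.ndarray] = []
        starts: list[int] = []
        for _, g in df.groupby("subject_id", sort=False):
            g = g[g["observation"] != "missing"]
            if len(g) < 2:
                continue
            grids.append(g["time"].to_numpy(dtype=float))
            starts.append(_STATE_INDEX[g["observation"].iloc[0]])
        n_sub = len(grids)
        max_len = max(len(t) for t in grids)
        dt_mat = np.full((n_sub, max_len - 1), np.nan)
        for i, t in enumerate(grids):
            dt_mat[i, : len(t) - 1] = np.round(np.diff(t), 9)
        start = np.array(starts)
        uniq_dts = np.unique(dt_mat[~np.isnan(dt_mat)])
        P_by_dt = {d: transition_probability(self.Q_, d) for d in uniq_dts}

        rng = np.random.default_rng(seed)
        reps = []
        dropped = 0
        sub = MultiStateMarkov(
            structure=self.mask_, t_report=self.t_report, init=self.Q_,
            gtol=self.gtol, maxiter=self.maxiter,
        )
        for _ in range(B):
            counts = self._simulate_counts(dt_mat, start, P_by_dt, rng)
            try:
                Qb, _, ok, _, _ = sub._fit_counts(counts)
            except (ValueError, np.linalg.LinAlgError):
                ok = False
            if not ok:
                dropped += 1
                continue
            reps.append(transition_probability(Qb, self.t_report))
        if dropped > max_dropped_frac * B:
            raise RuntimeError(
                f"{dropped}/{B} bootstrap replicates failed to converge"
            )
        stack = np.stack(reps)
        lower = np.percentile(stack, 2.5, axis=0)
        upper = np.percentile(stack, 97.5, axis=0)
        self.ci_ = (lower, upper)
        self.n_bootstrap_dropped_ = dropped
        return lower, upper

    @staticmethod
    def _simulate_counts(dt_mat, start, P_by_dt, rng):
        n_sub, n_int = dt_mat.shape
        state = start.copy()
        alive = np.ones(n_sub, dtype=bool)
        counts: dict[tuple[float, int, int], int] = {}
        for k in range(n_int):
            dts = dt_mat[:, k]
            active = alive & ~np.isnan(dts)
            if not active.any():
                break
            for d in np.unique(dts[active]):
                sel = active & (dts == d)
                cum = np.cumsum(P_by_dt[d], axis=1)
                u = rng.random(sel.sum())
                nxt = (u[:, None] > cum[state[sel]]).sum(axis=1)
                pairs, cnt = np.unique(
                    np.stack([state[sel], nxt]), axis=1, return_counts=True
                )
                for (a, b), c in zip(pairs.T, cnt):
                    key = (float(d), int(a), int(b))
                    counts[key] = counts.get(key, 0) + int(c)
                state[sel] = nxt
            alive &= state != DIED
        return counts


@dataclass
class FitResult:
    """Point estimates and diagnostics of a fitted multi-state model."""

    Q: np.ndarray
    P: np.ndarray
    log_likelihood: float
    converged: bool
    t_report: float
    ci: tuple[np.ndarray, np.ndarray] | None = None


def fit_model(panel: pd.DataFrame, structure="adjacent", **options) -> FitResult:
    """Functional wrapper over :class:`MultiStateMarkov`."""
    est = MultiStateMarkov(structure=structure, **options).fit(panel)
    return FitResult(
        Q=est.Q_, P=est.P_, log_likelihood=est.log_likelihood_,
        converged=est.converged_, t_report=est.t_report,
    )


def bootstrap_ci(panel: pd.DataFrame, fit: FitResult, B: int = 500,
                 seed: int | None = None):
    """Parametric-bootstrap CIs for a :class:`FitResult` (see estimator method)."""
    mask = np.zeros((N_STATES, N_STATES), dtype=bool)
    off = ~np.eye(N_STATES, dtype=bool)
    mask[off] = fit.Q[off] > 0
    mask[DIED] = False
    est = MultiStateMarkov(structure=mask, t_report=fit.t_report, init=fit.Q)
    est.fit(panel)
    lower, upper = est.bootstrap_ci(panel, B=B, seed=seed)
    fit.ci = (lower, upper)
    return lower, upper
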