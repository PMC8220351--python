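"""Multi-state Markov model: interval law, calibration, likelihood, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from frailkit.msm import (
    MultiStateMarkov,
    fit_model,
    log_likelihood,
    nearest_generator,
    structure_mask,
    transition_probability,
)
from frailkit.simulate import SimConfig, simulate_cohort, to_model_panel


def _random_generator(rng, structure="full"):
    mask = structure_mask(structure)
    Q = np.zeros((4, 4))
    Q[mask] = rng.uniform(0.02, 0.4, size=int(mask.sum()))
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class TestTransitionProbability:
    def test_zero_generator_gives_identity(self):
        np.testing.assert_allclose(transition_probability(np.zeros((4, 4)), 3.0), np.eye(4))

    def test_single_intensity_closed_form(self):
        """One escape rate lambda: escape probability is 1 - exp(-lambda t)."""
        lam, t = 0.5, 2.0
        Q = np.zeros((4, 4))
        Q[0, 1] = lam
        Q[0, 0] = -lam
        P = transition_probability(Q, t)
        assert P[0, 1] == pytest.approx(1 - np.exp(-lam * t), abs=1e-9)
        assert P[0, 1] == pytest.approx(0.632121, abs=1e-6)

    def test_chapman_kolmogorov(self):
        Q = _random_generator(np.random.default_rng(4))
        P2, P4 = transition_probability(Q, 2.0), transition_probability(Q, 4.0)
        np.testing.assert_allclose(P4, P2 @ P2, atol=1e-8)

    def test_invariants_and_errors(self):
        Q = _random_generator(np.random.default_rng(5))
        P = transition_probability(Q, 2.0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert ((P >= 0) & (P <= 1)).all()
        np.testing.assert_allclose(P[3], [0, 0, 0, 1], atol=1e-12)
        with pytest.raises(ValueError):
            transition_probability(Q, -1.0)
        with pytest.raises(ValueError):
            transition_probability(np.ones((4, 4)), 1.0)


class TestNearestGenerator:
    def test_identity_maps_to_zero(self):
        res = nearest_generator(np.eye(4), 2.0)
        np.testing.assert_allclose(res.Q, 0.0, atol=1e-12)
        assert res.max_abs_error < 1e-12

    def test_roundtrip_recovers_generator(self):
        Q = _random_generator(np.random.default_rng(8))
        P = transition_probability(Q, 2.0)
        res = nearest_generator(P, 2.0)
        np.testing.assert_allclose(res.Q, Q, atol=1e-8)
        assert res.max_abs_error < 1e-10

    def test_non_stochastic_input_rejected(self):
        with pytest.raises(ValueError, match="row-stochastic"):
            nearest_generator(np.full((4, 4), 0.3), 2.0)


class TestLogLikelihood:
    def test_empty_panel_is_zero(self):
        empty = pd.DataFrame(columns=["subject_id", "time_years", "observation"])
        assert log_likelihood(_random_generator(np.random.default_rng(0)), empty) == 0.0

    def test_single_interval_term(self, adjacent_generator):
        panel = pd.DataFrame(
            {"subject_id": [1, 1], "time_years": [0.0, 2.0],
             "observation": ["fit", "fit"]}
        )
        expected = np.log(expm(adjacent_generator * 2.0)[0, 0])
        assert log_likelihood(adjacent_generator, panel) == pytest.approx(expected)

    def test_toy_panel_hand_product(self, toy_panel, adjacent_generator):
        """Product of interval terms, death interval-censored, missing skipped."""
        P2 = expm(adjacent_generator * 2.0)
        P4 = expm(adjacent_generator * 4.0)
        hand = (
            np.log(P2[0, 0])       # a: fit -> fit over 2y
            + np.log(P2[0, 3])     # b: fit -> died by 2y (any path)
            + np.log(P4[1, 2])     # c: vulnerable -> frail over 4y (missing skipped)
        )
        assert log_likelihood(adjacent_generator, toy_panel) == pytest.approx(hand)

    def test_structural_zero_gives_minus_inf_with_diagnostic(self):
        Q = np.zeros((4, 4))
        Q[0, 3] = 0.1
        Q[0, 0] = -0.1
        panel = pd.DataFrame(
            {"subject_id": [1, 1], "time_years": [0.0, 2.0],
             "observation": ["vulnerable", "frail"]}
        )
        with pytest.warns(RuntimeWarning, match="zero probability"):
            assert log_likelihood(Q, panel) == -np.inf

    def test_splitting_record_at_missing_wave_is_invariant(self, adjacent_generator):
        joined = pd.DataFrame(
            {"subject_id": [1] * 4,
             "time_years": [0.0, 2.0, 4.0, 6.0],
             "observation": ["fit", "missing", "vulnerable", "frail"]}
        )
        split = pd.DataFrame(
            {"subject_id": [1, 1, 2, 2],
             "time_years": [0.0, 4.0, 4.0, 6.0],
             "observation": ["fit", "vulnerable", "vulnerable", "frail"]}
        )
        assert log_likelihood(adjacent_generator, joined) == pytest.approx(
            log_likelihood(adjacent_generator, split)
        )

    def test_observation_after_death_rejected(self):
        panel = pd.DataFrame(
            {"subject_id": [1, 1, 1], "time_years": [0.0, 2.0, 4.0],
             "observation": ["fit", "died", "fit"]}
        )
        with pytest.raises(ValueError, match="death"):
            log_likelihood(np.zeros((4, 4)), panel)


class TestFit:
    def test_two_state_closed_form(self):
        """k of n switch in one interval: fitted interval probability = k/n."""
        n, k = 100, 23
        obs = ["vulnerable"] * k + ["fit"] * (n - k)
        panel = pd.DataFrame(
            {"subject_id": np.repeat(np.arange(n), 2),
             "time_years": np.tile([0.0, 2.0], n),
             "observation": np.stack([["fit"] * n, obs], axis=1).reshape(-1)}
        )
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 1] = True
        est = MultiStateMarkov(structure=mask).fit(panel)
        assert est.converged_
        assert est.P_[0, 1] == pytest.approx(k / n, abs=1e-6)

    def test_recovery_from_known_generator(self, adjacent_generator):
        cfg = SimConfig(n_subjects=2_000, n_waves=5, generator=adjacent_generator,
                        missing_hazard=0.05, seed=31)
        panel = to_model_panel(simulate_cohort(cfg))
        est = MultiStateMarkov(structure="adjacent").fit(panel)
        target = transition_probability(adjacent_generator, 2.0)
        assert est.converged_
        assert np.abs(est.P_ - target).max() < 0.03

    def test_invariant_to_relabelling_and_order(self, adjacent_generator):
        cfg = SimConfig(n_subjects=300, generator=adjacent_generator, seed=41)
        panel = to_model_panel(simulate_cohort(cfg))
        shuffled = panel.sample(frac=1.0, random_state=0).sort_values(
            ["subject_id", "time_years"], kind="stable"
        )
        relabelled = shuffled.assign(
            subject_id=shuffled["subject_id"].map(lambda s: f"x{s}")
        )
        a = MultiStateMarkov().fit(panel)
        b = MultiStateMarkov().fit(relabelled)
        np.testing.assert_allclose(a.Q_, b.Q_, atol=1e-10)

    def test_functional_wrapper(self, adjacent_generator):
        cfg = SimConfig(n_subjects=300, generator=adjacent_generator, seed=43)
        panel = to_model_panel(simulate_cohort(cfg))
        result = fit_model(panel)
        assert result.converged
        np.testing.assert_allclose(result.P.sum(axis=1), 1.0, atol=1e-9)

    def test_sparse_intensities_flagged(self):
        panel = pd.DataFrame(
            {"subject_id": [1, 1], "time_years": [0.0, 2.0],
             "observation": ["fit", "fit"]}
        )
        est = MultiStateMarkov().fit(panel)
        assert ("vulnerable", "frail") in est.flagged_intensities_


class TestBootstrap:
    @pytest.fixture(scope="class")
    def fitted(self):
        Q = np.array(
            [[-0.33, 0.31, 0.00, 0.02],
             [0.20, -0.37, 0.15, 0.02],
             [0.00, 0.16, -0.31, 0.15],
             [0.00, 0.00, 0.00, 0.00]]
        )
        cfg = SimConfig(n_subjects=400, n_waves=3, generator=Q,
                        missing_hazard=0.05, seed=51)
        panel = to_model_panel(simulate_cohort(cfg))
        est = MultiStateMarkov(structure="adjacent", gtol=1e-6).fit(panel)
        return panel, est

    def test_percentile_bounds_bracket_point(self, fitted):
        panel, est = fitted
        lower, upper = est.bootstrap_ci(panel, B=30, seed=2)
        assert (lower <= upper + 1e-12).all()
        assert ((lower >= 0) & (upper <= 1)).all()
        for a, b in [(0, 1), (1, 0), (1, 2), (2, 3)]:
            assert lower[a, b] <= est.P_[a, b] <= upper[a, b]

    def test_reproducible_given_seed(self, fitted):
        panel, est = fitted
        ci1 = est.bootstrap_ci(panel, B=10, seed=9)
        ci2 = est.bootstrap_ci(panel, B=10, seed=9)
        np.testing.assert_array_equal(ci1[0], ci2[0])
        np.testing.assert_array_equal(ci1[1], ci2[1])

    def test_width_shrinks_with_sample_size(self):
        """CI width roughly halves when n quadruples (1/sqrt(n) scaling)."""
        Q = np.array(
            [[-0.33, 0.31, 0.00, 0.02],
             [0.20, -0.37, 0.15, 0.02],
             [0.00, 0.16, -0.31, 0.15],
             [0.00, 0.00, 0.00, 0.00]]
        )
        widths = {}
        for n in (400, 1600):
            cfg = SimConfig(n_subjects=n, n_waves=3, generator=Q,
                            missing_hazard=0.0, seed=61)
            panel = to_model_panel(simulate_cohort(cfg))
            est = MultiStateMarkov(structure="adjacent", gtol=1e-6).fit(panel)
            lower, upper = est.bootstrap_ci(panel, B=100, seed=3)
            widths[n] = upper[0, 1] - lower[0, 1]
        ratio = widths[1600] / widths[400]
        assert 0.5 * 0.7 < ratio < 0.5 * 1.3

    def test_b_too_small_rejected(self, fitted):
        panel, est = fitted
        with pytest.raises(ValueError):
            est.bootstrap_ci(panel, B=1)
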