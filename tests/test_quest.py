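"""QUEST+ engine: Bayes updates, entropy-based placement, recovery behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saccs.psychometric import ContrastValue, PsychometricParams, slope_to_width, weibull_prob
from saccs import quest as qp


def toy_grid(**kw):
    defaults = dict(
        thresholds=(math.log(0.01), math.log(0.1)),
        slopes=(2.0,),
        gamma_fixed=0.0,
        lam_fixed=0.0,
    )
    defaults.update(kw)
    return qp.ParameterGrid(**defaults)


class TestInit:
    def test_uniform_prior_on_default_grid(self):
        state = qp.init_state(qp.default_grid())
        assert state.posterior.shape == (15, 11)
        assert np.allclose(state.posterior, 1.0 / 165)
        assert state.trial_count == 0

    def test_single_cell_grid(self):
        g = qp.ParameterGrid(thresholds=(math.log(0.1),), slopes=(2.0,))
        state = qp.init_state(g)
        assert state.posterior.shape == (1, 1)
        assert state.posterior[0, 0] == 1.0

    def test_custom_prior_renormalised(self):
        g = toy_grid()
        state = qp.init_state(g, prior=np.array([[2.0], [6.0]]))
        assert np.allclose(state.posterior, [[0.25], [0.75]])

    def test_malformed_prior_rejected(self):
        g = toy_grid()
        with pytest.raises(ValueError):
            qp.init_state(g, prior=np.ones((3, 1)))
        with pytest.raises(ValueError):
            qp.init_state(g, prior=np.array([[-1.0], [2.0]]))

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            qp.ParameterGrid(thresholds=(0.0, -1.0), slopes=(1.0,))
        with pytest.raises(ValueError):
            qp.ParameterGrid(thresholds=(), slopes=(1.0,))


class TestLikelihood:
    def test_half_at_threshold_stimulus(self):
        g = toy_grid()
        state = qp.init_state(g)
        p = qp.outcome_likelihood(state, ContrastValue(0.01), 0, 0, correct=True)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_binary_outcomes_sum_to_one(self):
        state = qp.init_state(qp.default_grid(gamma_fixed=0.25))
        x = ContrastValue(0.05)
        for i, j in [(0, 0), (7, 5), (14, 10)]:
            pc = qp.outcome_likelihood(state, x, i, j, True)
            pi = qp.outcome_likelihood(state, x, i, j, False)
            assert pc + pi == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_weibull_evaluation(self):
        """Engine likelihoods equal the psychometric function with w = c/s."""
        rng = np.random.default_rng(11)
        grid = qp.default_grid(gamma_fixed=0.25, lam_fixed=0.02)
        state = qp.init_state(grid)
        for _ in range(20):
            i = rng.integers(0, 15)
            j = rng.integers(0, 11)
            x = float(rng.choice(qp.CONTRAST_LEVELS))
            expected = weibull_prob(
                x,
                PsychometricParams(
                    m=grid.thresholds[i],
                    w=slope_to_width(grid.slopes[j]),
                    gamma=0.25,
                    lam=0.02,
                ),
            )
            got = qp.outcome_likelihood(state, ContrastValue(x), int(i), int(j), True)
            assert got == pytest.approx(expected, abs=1e-12)


class TestUpdate:
    def test_hand_computed_bayes_on_two_cell_grid(self):
        """One correct response at high contrast, posterior by hand."""
        g = toy_grid()  # thresholds log(0.01), log(0.1); slope 2
        state = qp.init_state(g)
        x = 0.1
        p0 = weibull_prob(x, PsychometricParams(m=math.log(0.01), w=slope_to_width(2.0)))
        p1 = weibull_prob(x, PsychometricParams(m=math.log(0.1), w=slope_to_width(2.0)))
        new = qp.update(state, ContrastValue(x), correct=True)
        expect = np.array([[p0], [p1]]) / (p0 + p1)
        assert np.allclose(new.posterior, expect, atol=1e-14)
        assert new.trial_count == 1

    def test_uninformative_outcome_leaves_posterior_unchanged(self):
        # gamma = 0.5, lam = 0.5 is degenerate; instead use a grid where the
        # stimulus sits at every cell's threshold -> likelihood 0.5 everywhere
        g = qp.ParameterGrid(thresholds=(math.log(0.05),), slopes=(1.0, 2.0, 3.0),
                             gamma_fixed=0.0, lam_fixed=0.0)
        state = qp.init_state(g)
        new = qp.update(state, ContrastValue(0.05), correct=True)
        assert np.allclose(new.posterior, state.posterior, atol=1e-14)

    def test_updates_commute(self):
        state = qp.init_state(qp.default_grid())
        a, b = ContrastValue(0.01), ContrastValue(0.2)
        p1 = qp.update(qp.update(state, a, True), b, False).posterior
        p2 = qp.update(qp.update(state, b, False), a, True).posterior
        assert np.allclose(p1, p2, atol=1e-12)

    @given(
        idx=st.integers(min_value=0, max_value=14),
        correct=st.booleans(),
        n=st.integers(min_value=1, max_value=8),
    )
    @settings(max_examples=40, deadline=None)
    def test_posterior_stays_normalised(self, idx, correct, n):
        state = qp.init_state(qp.default_grid())
        x = ContrastValue(qp.CONTRAST_LEVELS[idx])
        for _ in range(n):
            state = qp.update(state, x, correct)
        assert state.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(state.posterior >= 0)


class TestNextStimulus:
    def test_brute_force_expected_entropy_on_toy_domain(self):
        """Exhaustive enumeration over stimulus x outcome branches."""
        g = qp.ParameterGrid(
            thresholds=(math.log(0.02), math.log(0.08), math.log(0.3)),
            slopes=(1.0, 3.0),
            gamma_fixed=0.0,
            lam_fixed=0.02,
        )
        domain = (0.01, 0.07, 0.4)
        state = qp.init_state(g, stimulus_domain=domain)
        state = qp.update(state, ContrastValue(0.07), True)

        def entropy(p):
            p = p[p > 0]
            return -(p * np.log(p)).sum()

        best_val, best_x = None, None
        for x in domain:
            exp_h = 0.0
            for correct in (True, False):
                joint = np.array(
                    [
                        [
                            state.posterior[i, j]
                            * qp.outcome_likelihood(state, ContrastValue(x), i, j, correct)
                            for j in range(2)
                        ]
                        for i in range(3)
                    ]
                )
                pz = joint.sum()
                if pz > 0:
                    exp_h += pz * entropy((joint / pz).ravel())
            if best_val is None or exp_h < best_val - 1e-12:
                best_val, best_x = exp_h, x
        assert qp.next_stimulus(state).c_linear == pytest.approx(best_x)

    def test_point_mass_posterior_tie_breaks_to_lowest_contrast(self):
        g = toy_grid()
        prior = np.zeros((2, 1))
        prior[1, 0] = 1.0
        state = qp.init_state(g, prior=prior, stimulus_domain=(0.05, 0.2, 0.6))
        assert qp.next_stimulus(state).c_linear == pytest.approx(0.05)

    def test_expected_entropy_never_exceeds_current(self):
        state = qp.init_state(qp.default_grid())
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = qp.next_stimulus(state)
            h_before = qp.posterior_entropy(state)
            # expected entropy over outcomes for the chosen stimulus
            lik = state._lik[list(state.stimulus_domain).index(x.c_linear)]
            pc = (lik * state.posterior).sum()
            jc = lik * state.posterior / pc
            ji = (1 - lik) * state.posterior / (1 - pc)

            def ent(p):
                p = p[p > 0]
                return -(p * np.log(p)).sum()

            exp_h = pc * ent(jc.ravel()) + (1 - pc) * ent(ji.ravel())
            assert exp_h <= h_before + 1e-9
            state = qp.update(state, x, bool(rng.random() < 0.7))

    def test_empty_domain_rejected(self):
        g = toy_grid()
        state = qp.init_state(g)
        object.__setattr__(state, "stimulus_domain", ())
        with pytest.raises(ValueError):
            qp.next_stimulus(state)


class TestEstimate:
    def test_point_mass_returns_that_threshold(self):
        g = toy_grid()
        prior = np.array([[0.0], [1.0]])
        state = qp.init_state(g, prior=prior)
        assert qp.estimate_threshold(state) == pytest.approx(math.log(0.1))

    def test_symmetric_posterior_returns_midpoint(self):
        g = toy_grid()
        state = qp.init_state(g, prior=np.array([[0.5], [0.5]]))
        mid = 0.5 * (math.log(0.01) + math.log(0.1))
        assert qp.estimate_threshold(state) == pytest.approx(mid)

    def test_matches_independent_weighted_sum(self):
        rng = np.random.default_rng(5)
        g = qp.default_grid()
        prior = rng.random((15, 11))
        state = qp.init_state(g, prior=prior)
        marg = state.posterior.sum(axis=1)
        expect = float(np.dot(marg, np.array(g.thresholds)))
        assert qp.estimate_threshold(state) == pytest.approx(expect, abs=1e-12)


class TestBehaviour:
    def test_marginal_entropy_decreases_on_average(self):
        """Threshold-marginal entropy shrinks across trials, averaged over
        100 simulated observers sitting on the grid."""
        rng = np.random.default_rng(42)
        n_rep, n_trials = 100, 30
        ent = np.zeros((n_rep, n_trials + 1))
        grid = qp.default_grid()
        for r in range(n_rep):
            i = rng.integers(0, 15)
            j = rng.integers(0, 11)
            truth = PsychometricParams(
                m=grid.thresholds[i], w=slope_to_width(grid.slopes[j]), lam=0.02
            )
            state = qp.init_state(grid)
            for t in range(n_trials):
                marg = qp.threshold_marginal(state)
                ent[r, t] = -(marg[marg > 0] * np.log(marg[marg > 0])).sum()
                x = qp.next_stimulus(state)
                state = qp.update(
                    state, x, bool(rng.random() < weibull_prob(x.c_linear, truth))
                )
            marg = qp.threshold_marginal(state)
            ent[r, -1] = -(marg[marg > 0] * np.log(marg[marg > 0])).sum()
        mean_ent = ent.mean(axis=0)
        # overall decrease, and no average step increases beyond noise
        assert mean_ent[-1] < 0.3 * mean_ent[0]
        assert np.all(np.diff(mean_ent) < 0.02)

    def test_4afc_engine_predicted_probability_floor(self):
        """With a 25% guessing floor no placement predicts below-chance success."""
        rng = np.random.default_rng(9)
        grid = qp.default_grid(gamma_fixed=0.25)
        state = qp.init_state(grid)
        for _ in range(20):
            x = qp.next_stimulus(state)
            k = list(state.stimulus_domain).index(x.c_linear)
            p_mean = float((state._lik[k] * state.posterior).sum())
            assert p_mean >= 0.25
            state = qp.update(state, x, bool(rng.random() < 0.6))


class TestSerialization:
    def test_json_round_trip(self):
        state = qp.init_state(qp.default_grid(gamma_fixed=0.25), location_label="meridian_90")
        state = qp.update(state, ContrastValue(0.05), True)
        back = qp.QuestState.from_json(state.to_json())
        assert back.trial_count == 1
        assert back.location_label == "meridian_90"
        assert np.allclose(back.posterior, state.posterior)
        assert back.grid == state.grid
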