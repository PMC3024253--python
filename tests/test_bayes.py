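"""Forgetting-Bayesian learner: updates, learning rates, jump inference."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from banditbayes import (
    ChoiceModelSpec,
    DirichletBelief,
    EnvironmentConfig,
    ForgettingBayesLearner,
    SoftmaxAgent,
    expected_value,
    forgetting_operator,
    init_belief,
    no_jump_probability,
    posterior_mean,
    update_chosen,
    update_unchosen,
)
from banditbayes.experiment import replay_diagnostics
from banditbayes.task import BLUE, RED, simulate_agent_session

UNIFORM = np.full(3, 1 / 3)


class TestInitBelief:
    def test_defaults_give_uniform_mean_and_unit_rate(self):
        b = init_belief()
        np.testing.assert_allclose(posterior_mean(b), UNIFORM)
        assert b.eta == 1.0
        np.testing.assert_allclose(b.nu0 * b.c0, np.ones(3))  # flat prior scale

    def test_prior_center_reproduced_before_data(self):
        c0 = np.array([0.5, 0.25, 0.25])
        b = init_belief(nu0=3.0, c0=c0)
        np.testing.assert_allclose(posterior_mean(b), c0)

    def test_rejects_non_simplex_center(self):
        with pytest.raises(ValueError):
            init_belief(c0=np.array([0.5, 0.5, 0.5]))


class TestNoJumpProbability:
    def test_uninformative_evidence_gives_prior_no_jump(self):
        """A fresh (maximal-risk) belief makes the outcome equally likely
        under stay and jump, so pi = 1 - q for any outcome."""
        b = init_belief()
        for q in (0.04, 0.16, 0.5):
            for x in range(3):
                assert no_jump_probability(b, x, q) == pytest.approx(1 - q)

    def test_surprising_outcome_lowers_pi(self):
        # belief concentrated on gain: alpha = (1, 1, 51)
        b = DirichletBelief(c0=UNIFORM, nu0=3.0, n=50.0, z=np.array([0.0, 0.0, 1.0]))
        np.testing.assert_allclose(b.alpha, [1.0, 1.0, 51.0])
        q = 0.16
        pi = no_jump_probability(b, 0, q)  # observed loss
        l_stay, l_jump = 1.0 / 53.0, 1.0 / 3.0
        expected = (1 - q) * l_stay / ((1 - q) * l_stay + q * l_jump)
        assert pi == pytest.approx(expected, rel=1e-12)
        assert pi < 1 - q

    def test_expected_outcome_raises_pi(self):
        b = DirichletBelief(c0=UNIFORM, nu0=3.0, n=50.0, z=np.array([0.0, 0.0, 1.0]))
        assert no_jump_probability(b, 2, 0.16) > 1 - 0.16

    def test_invalid_hazard_rejected(self):
        with pytest.raises(ValueError):
            no_jump_probability(init_belief(), 0, 0.0)

    @given(st.floats(0.01, 0.99), st.integers(0, 2))
    def test_pi_strictly_between_zero_and_one(self, q, x):
        b = DirichletBelief(c0=UNIFORM, nu0=3.0, n=20.0, z=np.array([0.7, 0.2, 0.1]))
        assert 0.0 < no_jump_probability(b, x, q) < 1.0


class TestUpdateChosen:
    def test_jump_free_rate_follows_one_over_t(self):
        """With pi = 1 the rate decays as 1/(T+1) and z is the running mean
        of the outcome indicators with the prior centre as first entry."""
        b = init_belief()
        outcomes = [2, 0, 2, 1, 2, 2, 0, 1, 2, 2]
        acc = [UNIFORM.copy()]
        for t, x in enumerate(outcomes, start=1):
            b = update_chosen(b, x, pi=1.0)
            e = np.zeros(3)
            e[x] = 1.0
            acc.append(e)
            assert b.eta == pytest.approx(1.0 / (t + 1))
            np.testing.assert_allclose(b.z, np.mean(acc, axis=0), atol=1e-12)

    def test_detected_jump_resets_learning(self):
        b = init_belief()
        for x in [2, 2, 2, 2, 2]:
            b = update_chosen(b, x, pi=0.95)
        b = update_chosen(b, 0, pi=1e-12)
        assert b.eta == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(b.z, [1.0, 0.0, 0.0], atol=1e-10)

    def test_recursion_matches_product_form(self, rng):
        """The recursive effective count equals its closed product form
        n_T = n_0 prod(pi) + sum over visits of the post-visit pi product."""
        for _ in range(50):
            T = 50
            visited = rng.random(T) < 0.4
            pis = rng.uniform(0.05, 1.0, T)
            b = init_belief()
            for t in range(T):
                if visited[t]:
                    b = update_chosen(b, int(rng.integers(3)), pis[t])
                else:
                    b = update_unchosen(b, pis[t])
            n_direct = np.prod(pis)
            for t in np.flatnonzero(visited):
                n_direct += np.prod(pis[t + 1 :])
            assert b.n == pytest.approx(n_direct, abs=1e-10)
            assert 0.0 < b.eta <= 1.0

    def test_rate_bounds_invariant(self, rng):
        b = init_belief()
        for _ in range(200):
            if rng.random() < 0.5:
                b = update_chosen(b, int(rng.integers(3)), rng.uniform(0.01, 1.0))
            else:
                b = update_unchosen(b, rng.uniform(0.01, 1.0))
            assert 0.0 < b.eta <= 1.0
            assert b.n >= 0.0
            assert abs(b.z.sum() - 1.0) < 1e-12


class TestUpdateUnchosen:
    def test_no_forgetting_without_jump_evidence(self):
        b = DirichletBelief(c0=UNIFORM, nu0=3.0, n=10.0, z=np.array([0.5, 0.3, 0.2]))
        b2 = update_unchosen(b, pi=1.0)
        assert b2.n == b.n
        np.testing.assert_allclose(b2.z, b.z)

    def test_decay_arithmetic(self):
        b = DirichletBelief(c0=UNIFORM, nu0=3.0, n=10.0, z=np.array([0.5, 0.3, 0.2]))
        assert update_unchosen(b, 0.5).n == pytest.approx(5.0)

    def test_unvisited_arm_relaxes_to_prior(self):
        """Geometric decay of n; posterior mean approaches the prior centre
        monotonically and the imaginary learning rate creeps back up."""
        b = DirichletBelief(c0=UNIFORM, nu0=3.0, n=40.0, z=np.array([0.8, 0.1, 0.1]))
        pi = 0.9
        dists, etas = [], []
        for k in range(1, 31):
            b = update_unchosen(b, pi)
            assert b.n == pytest.approx(40.0 * pi**k, rel=1e-12)
            dists.append(np.abs(posterior_mean(b) - UNIFORM).sum())
            etas.append(b.eta)
        assert np.all(np.diff(dists) <= 1e-15)
        assert np.all(np.diff(etas) >= -1e-15)


class TestPosteriorMean:
    def test_hand_arithmetic(self):
        b = DirichletBelief(c0=UNIFORM, nu0=3.0, n=6.0, z=np.array([0.5, 0.5, 0.0]))
        np.testing.assert_allclose(posterior_mean(b), [4 / 9, 4 / 9, 1 / 9])

    def test_data_dominated_limit(self):
        z = np.array([0.2, 0.3, 0.5])
        b = DirichletBelief(c0=UNIFORM, nu0=3.0, n=1e9, z=z)
        np.testing.assert_allclose(posterior_mean(b), z, atol=1e-8)


class TestForgettingOperator:
    def test_limits(self):
        a1, a0 = np.array([2.0, 3.0, 4.0]), np.ones(3)
        np.testing.assert_allclose(forgetting_operator(a1, a0, 1.0), a1)
        np.testing.assert_allclose(forgetting_operator(a1, a0, 0.0), a0)

    def test_geometric_mean_log_density_identity(self, rng):
        """The mixed Dirichlet's log-density equals pi*logf1 + (1-pi)*logf0
        up to a normalising constant, pointwise on the simplex."""
        a1, a0, pi = np.array([2.0, 3.0, 4.0]), np.ones(3), 0.5
        mixed = forgetting_operator(a1, a0, pi)
        np.testing.assert_allclose(mixed, [1.5, 2.0, 2.5])
        xs = rng.dirichlet(np.ones(3), size=20)
        gaps = [
            stats.dirichlet.logpdf(x, mixed)
            - pi * stats.dirichlet.logpdf(x, a1)
            - (1 - pi) * stats.dirichlet.logpdf(x, a0)
            for x in xs
        ]
        assert np.ptp(gaps) < 1e-10

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            forgetting_operator(np.array([0.0, 1.0, 1.0]), np.ones(3), 0.5)


class TestExpectedValue:
    def test_symmetry_and_degenerate(self):
        b = init_belief()
        assert expected_value(b, (-1, 0, 1)) == pytest.approx(0.0)
        sharp = DirichletBelief(
            c0=UNIFORM, nu0=3.0, n=1e12, z=np.array([0.0, 0.0, 1.0])
        )
        assert expected_value(sharp, (-2, 0, 2)) == pytest.approx(2.0, abs=1e-9)

    def test_dot_product(self):
        b = DirichletBelief(c0=UNIFORM, nu0=3.0, n=1e12, z=np.array([0.2, 0.3, 0.5]))
        assert expected_value(b, (-1, 0, 1)) == pytest.approx(0.3, abs=1e-9)


def test_jump_free_updating_matches_conjugate_oracle(rng):
    """With pi = 1 throughout, the learner's posterior means equal exact
    conjugate Dirichlet-multinomial updating with prior (nu0+1)*c0."""
    for _ in range(20):
        nu0 = 3.0
        beliefs = [init_belief(nu0) for _ in range(6)]
        counts = np.zeros((6, 3))
        prior = (nu0 + 1.0) * UNIFORM
        for _t in range(60):
            arm = int(rng.integers(6))
            x = int(rng.integers(3))
            beliefs = [
                update_chosen(b, x, 1.0) if j == arm else update_unchosen(b, 1.0)
                for j, b in enumerate(beliefs)
            ]
            counts[arm, x] += 1
            for j in range(6):
                conj = (prior + counts[j]) / (prior + counts[j]).sum()
                np.testing.assert_allclose(posterior_mean(beliefs[j]), conj, atol=1e-10)


def test_learner_observe_extrapolates_within_color(config):
    """The chosen colour's arms all decay by the inferred pi; the other
    colour decays by its prior no-jump probability."""
    learner = ForgettingBayesLearner(config)
    n_before = np.array([b.n for b in learner.beliefs])
    diag = learner.observe(0, 2)  # arm 0 is blue
    n_after = np.array([b.n for b in learner.beliefs])
    pi_b, pi_r = diag["pi_blue"], diag["pi_red"]
    assert pi_r == pytest.approx(1 - config.hazard_red)
    np.testing.assert_allclose(n_after[0], pi_b * n_before[0] + 1.0)
    np.testing.assert_allclose(n_after[1:3], pi_b * n_before[1:3])
    np.testing.assert_allclose(n_after[3:], pi_r * n_before[3:])


def test_pi_detects_true_jumps(config):
    """Unexpected uncertainty 1 - pi is higher on trials when the chosen
    colour truly jumped than when it did not (detection validity)."""
    env = EnvironmentConfig(n_trials=2000)
    agent = SoftmaxAgent(ChoiceModelSpec("bayes"), {"beta": 5.0}, env)
    session = simulate_agent_session(env, agent, seed=99)
    diag = replay_diagnostics(session, config=env)
    chosen_pi = np.where(
        session["color"] == BLUE, diag["pi_blue"], diag["pi_red"]
    )
    jumped = np.where(
        session["color"] == BLUE, session["jump_blue"], session["jump_red"]
    ).astype(bool)
    assert (1 - chosen_pi[jumped]).mean() > (1 - chosen_pi[~jumped]).mean()
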