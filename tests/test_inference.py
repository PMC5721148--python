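"""Belief updating, expected free energy, policy/γ inference, and oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

from epiforage import (
    CategoricalTable,
    GenerativeModel,
    InitialBelief,
    PolicySpace,
    PrecisionSet,
    PreferenceVector,
    TransitionTable,
    bayesian_model_average,
    enumerate_efe,
    exact_posterior_oracle,
    expected_free_energy,
    expected_outcomes,
    forward_backward_posterior,
    infer_gamma,
    make_fixture,
    select_action,
    softmax,
    update_gamma,
    update_policy_posterior,
    update_state_beliefs,
)
from epiforage.inference import PolicyPosterior


def single_factor_model(A_cols, prior=None, B=None):
    A_cols = np.asarray(A_cols, dtype=float)
    n = A_cols.shape[1]
    return GenerativeModel(
        A=CategoricalTable([A_cols]),
        B=TransitionTable([(np.eye(n) if B is None else np.asarray(B))[:, :, None]]),
        C=PreferenceVector.uniform([A_cols.shape[0]]),
        D=InitialBelief([np.full(n, 1.0 / n) if prior is None else np.asarray(prior)]),
        policies=PolicySpace.single_step(1),
        gamma_prior=1.0,
    )


class TestUpdateStateBeliefs:
    def test_delta_likelihood_gives_onehot_posterior(self):
        m = single_factor_model(np.eye(3))
        b, _, _ = update_state_beliefs(m, [[1]], [0], iters=32)
        assert b.s[0][0][1] > 1 - 1e-4

    def test_uniform_likelihood_returns_transition_propagated_prior(self):
        # uninformative data: filtered beliefs follow the prior's propagation
        B = np.array([[0.7, 0.2], [0.3, 0.8]])
        m = single_factor_model(np.full((2, 2), 0.5), prior=[0.9, 0.1], B=B)
        b, _, _ = update_state_beliefs(m, [[0], [1]], [0], iters=64, window=1)
        np.testing.assert_allclose(b.s[0][0], [0.9, 0.1], atol=1e-8)
        np.testing.assert_allclose(b.s[1][0], B @ np.array([0.9, 0.1]), atol=1e-8)

    def test_converges_to_exact_posterior(self, kl_div):
        m = make_fixture(7)
        obs = np.array([[0, 1], [2, 0]])
        b, _, _ = update_state_beliefs(m, obs, [1], iters=64)
        marg, _ = exact_posterior_oracle(m, obs, [1])
        for t in range(2):
            for f in range(2):
                assert kl_div(marg[t][f], b.s[t][f]) < 1e-3

    def test_free_energy_nonincreasing(self):
        for seed in range(10):
            m = make_fixture(seed)
            rng = np.random.default_rng(seed)
            obs = np.stack([rng.integers(0, 3, 3), rng.integers(0, 2, 3)], axis=1)
            _, _, F = update_state_beliefs(m, obs, rng.integers(0, 2, 2), iters=32)
            assert np.all(np.diff(F) <= 1e-6)

    def test_depolarization_softmax_matches_beliefs(self):
        m = make_fixture(3)
        b, depol, _ = update_state_beliefs(m, [[0, 1]], [0], iters=16)
        for t in range(len(b.s)):
            for f in range(2):
                np.testing.assert_allclose(softmax(depol.v[t][f]), b.s[t][f], atol=1e-8)

    def test_invalid_step_rejected(self):
        m = make_fixture(0)
        with pytest.raises(ValueError):
            update_state_beliefs(m, [[0, 0]], [0], step=1.5)


class TestExpectedOutcomes:
    def test_onehot_belief_deterministic_likelihood(self):
        m = single_factor_model(np.eye(3))
        (qo,) = expected_outcomes([np.array([0.0, 1.0, 0.0])], m)
        np.testing.assert_allclose(qo, [0, 1, 0], atol=1e-12)

    def test_uniform_belief_gives_column_average(self):
        A = np.array([[0.9, 0.2], [0.1, 0.8]])
        m = single_factor_model(A)
        (qo,) = expected_outcomes([np.array([0.5, 0.5])], m)
        np.testing.assert_allclose(qo, A.mean(axis=1), atol=1e-12)

    def test_hand_mixture(self):
        # belief [0.5, 0.5], columns [0.9,0.1] and [0.2,0.8] -> [0.55, 0.45]
        m = single_factor_model(np.array([[0.9, 0.2], [0.1, 0.8]]))
        (qo,) = expected_outcomes([np.array([0.5, 0.5])], m)
        np.testing.assert_allclose(qo, [0.55, 0.45], atol=1e-12)


class TestExpectedFreeEnergy:
    def test_uniform_likelihood_zero_epistemic(self):
        m = single_factor_model(np.full((3, 3), 1 / 3))
        res = expected_free_energy(m, [np.full(3, 1 / 3)], [0])
        assert abs(res.decompositions[0].epistemic) < 1e-10

    def test_deterministic_likelihood_uniform_belief_ln3(self):
        m = single_factor_model(np.eye(3))
        res = expected_free_energy(m, [np.full(3, 1 / 3)], [0])
        assert abs(res.decompositions[0].epistemic - np.log(3)) < 1e-10

    def test_onehot_belief_zero_epistemic(self):
        # a fully resolved state has no further information to offer
        m = single_factor_model(np.array([[0.9, 0.2], [0.1, 0.8]]))
        res = expected_free_energy(m, [np.array([1.0, 0.0])], [0])
        assert abs(res.decompositions[0].epistemic) < 1e-10

    def test_empty_policy_rejected(self):
        m = single_factor_model(np.eye(2))
        with pytest.raises(ValueError):
            expected_free_energy(m, [np.array([0.5, 0.5])], [])

    def test_components_recombine_and_match_enumeration(self):
        for seed in range(20):
            m = make_fixture(seed)
            rng = np.random.default_rng(seed)
            qs = [rng.dirichlet(np.ones(n)) for n in m.factor_sizes]
            res = expected_free_energy(m, qs, [0, 1])
            bf = enumerate_efe(m, qs, [0, 1])
            for d, e in zip(res.decompositions, bf.decompositions):
                assert d.epistemic >= -1e-10
                assert d.ambiguity >= 0
                assert abs(d.G - (-d.pragmatic - d.epistemic)) < 1e-8
                assert abs(d.epistemic - e.epistemic) < 1e-8
            np.testing.assert_allclose(res.G_per_tau, bf.G_per_tau, atol=1e-8)

    def test_uniform_preferences_make_pragmatic_constant(self):
        m = make_fixture(11)
        rng = np.random.default_rng(0)
        qs = [rng.dirichlet(np.ones(n)) for n in m.factor_sizes]
        prag = [
            expected_free_energy(m, qs, [a]).decompositions[0].pragmatic
            for a in range(m.n_actions)
        ]
        assert max(prag) - min(prag) < 1e-10

    def test_raising_zeta_raises_epistemic_value(self):
        # salience of an unresolved state grows with its sensory precision
        vals = []
        for z in (0.25, 0.5, 1.0, 2.0, 4.0):
            m = single_factor_model(np.array([[0.8, 0.1], [0.2, 0.9]]))
            m.precision = PrecisionSet(zeta=np.array([z, z]), zeta_factor=0, zeta_modalities=(0,))
            res = expected_free_energy(m, [np.array([0.5, 0.5])], [0])
            vals.append(res.decompositions[0].epistemic)
        assert np.all(np.diff(vals) > 0)


class TestPolicyPosterior:
    def test_zero_gamma_uniform(self):
        pp = update_policy_posterior(np.zeros(3), np.array([1.0, 5.0, 2.0]), 0.0)
        np.testing.assert_allclose(pp.pi, np.full(3, 1 / 3), atol=1e-12)

    def test_equal_G_symmetric(self):
        pp = update_policy_posterior(np.zeros(2), np.array([1.0, 1.0]), 4.0)
        np.testing.assert_allclose(pp.pi, [0.5, 0.5], atol=1e-12)

    def test_hand_softmax(self):
        pp = update_policy_posterior(np.zeros(2), np.array([1.0, 2.0]), 1.0)
        np.testing.assert_allclose(pp.pi, [0.73105858, 0.26894142], atol=1e-7)

    def test_invariant_to_constant_shift_of_G(self):
        G = np.array([0.3, 1.2, 0.7])
        a = update_policy_posterior(np.zeros(3), G, 8.0).pi
        b = update_policy_posterior(np.zeros(3), G + 5.0, 8.0).pi
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            update_policy_posterior(np.zeros(2), np.zeros(3), 1.0)


class TestGamma:
    def test_identical_G_keeps_gamma_at_prior(self):
        G = np.array([1.0, 1.0, 1.0])
        gamma = infer_gamma(np.zeros(3), G, beta0=1 / 16)
        assert abs(gamma - 16.0) < 1e-8

    def test_fixed_point_stationary(self):
        F = np.array([0.2, 0.8])
        G = np.array([0.0, 2.0])
        gamma = infer_gamma(F, G, beta0=0.5, iters=200)
        beta = 1 / gamma
        pi = softmax(-F - gamma * G)
        pi0 = softmax(-gamma * G)
        new = update_gamma(pi, pi0, G, beta, 0.5)
        assert abs(new - gamma) < 1e-6

    def test_matches_root_finder(self):
        F = np.array([0.2, 0.8])
        G = np.array([0.0, 2.0])
        beta0 = 0.5

        def resid(beta):
            g = 1 / beta
            pi = softmax(-F - g * G)
            pi0 = softmax(-g * G)
            return beta - beta0 - (pi - pi0) @ G

        beta_star = brentq(resid, 1e-3, 10.0)
        gamma = infer_gamma(F, G, beta0=beta0, iters=500)
        assert abs(1 / gamma - beta_star) < 1e-6


class TestSelectAction:
    def policies(self):
        return PolicySpace(np.array([[0], [1], [2]]))

    def test_onehot_posterior_both_modes(self):
        pp = PolicyPosterior(pi=[0, 1, 0], F=np.zeros(3), G=np.zeros(3), gamma=1.0)
        assert select_action(pp, self.policies(), "map") == 1
        rng = np.random.default_rng(0)
        assert select_action(pp, self.policies(), "sample", rng) == 1

    def test_map_tie_breaks_to_lowest_index(self):
        pp = PolicyPosterior(pi=[0.5, 0.5, 0.0], F=np.zeros(3), G=np.zeros(3), gamma=1.0)
        assert select_action(pp, self.policies(), "map") == 0

    def test_sample_reproducible_with_seed(self):
        pp = PolicyPosterior(pi=[0.3, 0.3, 0.4], F=np.zeros(3), G=np.zeros(3), gamma=1.0)
        a = [select_action(pp, self.policies(), "sample", np.random.default_rng(5)) for _ in range(10)]
        b = [select_action(pp, self.policies(), "sample", np.random.default_rng(5)) for _ in range(10)]
        assert a == b

    def test_unknown_mode_rejected(self):
        pp = PolicyPosterior(pi=[1.0], F=np.zeros(1), G=np.zeros(1), gamma=1.0)
        with pytest.raises(ValueError):
            select_action(pp, PolicySpace(np.array([[0]])), "greedy")


class TestExactOracle:
    def test_deterministic_likelihood_onehot(self, two_state_model):
        m = two_state_model
        m.A.values[0] = np.eye(2)
        marg, _ = exact_posterior_oracle(m, [[1]], [0])
        np.testing.assert_allclose(marg[0][0], [0, 1], atol=1e-12)

    def test_uniform_likelihood_returns_prior(self, two_state_model):
        m = two_state_model
        m.A.values[0] = np.full((2, 2), 0.5)
        m.D.values[0] = np.array([0.3, 0.7])
        marg, _ = exact_posterior_oracle(m, [[0]], [0])
        np.testing.assert_allclose(marg[0][0], [0.3, 0.7], atol=1e-12)

    def test_bayes_rule_by_hand(self, two_state_model):
        marg, _ = exact_posterior_oracle(two_state_model, [[0]], [0])
        np.testing.assert_allclose(marg[0][0], [0.81818182, 0.18181818], atol=1e-7)

    def test_refuses_oversized_state_space(self):
        m = make_fixture(0)
        obs = np.zeros((3, 2), dtype=int)
        with pytest.raises(ValueError, match="refuses"):
            exact_posterior_oracle(m, obs, [0, 0], max_trajectories=10)

    def test_forward_backward_matches_enumeration(self, kl_div):
        for seed in (1, 2, 3):
            m = make_fixture(seed)
            rng = np.random.default_rng(seed)
            obs = np.stack([rng.integers(0, 3, 3), rng.integers(0, 2, 3)], axis=1)
            pol = rng.integers(0, 2, 2)
            marg_fb, _, logz_fb = forward_backward_posterior(m, obs, pol)
            marg_en, logz_en = exact_posterior_oracle(m, obs, pol)
            assert abs(logz_fb - logz_en) < 1e-8
            for t in range(3):
                for f in range(2):
                    np.testing.assert_allclose(marg_fb[t][f], marg_en[t][f], atol=1e-8)


class TestBeliefSerialization:
    def test_long_format_roundtrips_values(self, tmp_path):
        from epiforage import beliefs_to_frame

        m = make_fixture(2)
        obs = np.array([[0, 1], [1, 0]])
        results = [update_state_beliefs(m, obs, [a], iters=8) for a in range(2)]
        df = beliefs_to_frame([r[0] for r in results], [r[2] for r in results])
        path = tmp_path / "beliefs.csv"
        df.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path, float_precision="round_trip")
        sel = back[(back.policy == 1) & (back.factor == "0") & (back.time == 1)]
        np.testing.assert_array_equal(sel["value"].to_numpy(), results[1][0].s[1][0])
        f_rows = back[back.factor == "F"]
        assert len(f_rows) == sum(len(r[2]) for r in results)


class TestBayesianModelAverage:
    def test_mixture_sums_and_weights(self):
        m = make_fixture(5)
        obs = np.array([[0, 1], [1, 0]])
        per_policy = [update_state_beliefs(m, obs, [a], iters=16)[0] for a in range(2)]
        pi = np.array([0.3, 0.7])
        marg = bayesian_model_average(per_policy, pi)
        for t in range(2):
            for f in range(2):
                expect = 0.3 * per_policy[0].s[t][f] + 0.7 * per_policy[1].s[t][f]
                np.testing.assert_allclose(marg[t][f], expect, atol=1e-10)
                assert abs(marg[t][f].sum() - 1.0) < 1e-10
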