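"""Greedy policy, baselines, provident DP against independent oracles."""

import numpy as np
import pytest
from scipy import integrate, stats

from flyforget.belief import BeliefState, stationary_belief
from flyforget.environment import (EnvParams, build_transition_matrix,
                                   emission_matrix)
from flyforget.policies import (ConstantPolicy, DPConfig, GreedyPolicy,
                                ImmediateForgettingPolicy, NoForgettingPolicy,
                                ProvidentPolicy, baseline_policies,
                                evaluate_total_reward,
                                immediate_expected_reinforcement,
                                provident_value, provident_thresholds,
                                reinforcement_weights)


def _simplex_grid(m):
    pts = [(i, j) for i in range(m + 1) for j in range(m + 1 - i)]
    return np.array([[i / m, 1 - (i + j) / m, j / m] for i, j in pts])


class TestImmediateExpectedReinforcement:
    @pytest.mark.parametrize("b, expected", [
        ((1.0, 0.0, 0.0), 1.0),
        ((0.0, 1.0, 0.0), 0.0),
        ((0.3, 0.5, 0.2), 0.1),
    ])
    def test_examples(self, env, b, expected):
        val = immediate_expected_reinforcement(BeliefState(np.array(b)), env)
        assert val == pytest.approx(expected, abs=1e-12)

    def test_zero_at_stationary_for_zero_average_reward(self, env):
        pi = stationary_belief(env)
        assert immediate_expected_reinforcement(pi, env) == pytest.approx(
            0.0, abs=1e-12)


class TestGreedyPolicy:
    def test_reward_belief_with_equal_costs(self, env):
        g = GreedyPolicy(env)
        b = BeliefState(np.array([0.4, 0.5, 0.1]))
        assert g.decide(b, 0.2, 0.2) == "ap"

    def test_cheaper_action_wins_at_zero_reinforcement(self, env):
        g = GreedyPolicy(env)
        b = BeliefState(np.array([0.2, 0.6, 0.2]))
        assert g.decide(b, 0.1, 0.3) == "ap"
        assert g.decide(b, 0.3, 0.1) == "av"

    def test_tie_breaks_toward_approach(self, env):
        g = GreedyPolicy(env)
        b = BeliefState(np.array([0.2, 0.6, 0.2]))
        assert g.decide(b, 0.25, 0.25) == "ap"

    def test_depends_only_on_cost_difference(self, env, rng):
        g = GreedyPolicy(env)
        for _ in range(100):
            b = BeliefState(rng.dirichlet([1, 1, 1]))
            c_ap, c_av = rng.exponential(0.3, 2)
            shift = rng.uniform(0, 5)
            assert g.decide(b, c_ap, c_av) == g.decide(b, c_ap + shift,
                                                       c_av + shift)


class TestProvidentDP:
    def test_horizon_limits(self):
        with pytest.raises(ValueError):
            DPConfig(horizon=8)
        with pytest.raises(ValueError):
            DPConfig(horizon=0)
        with pytest.raises(ValueError):
            DPConfig(gamma=1.0)

    def test_single_step_reduction(self, env, costs):
        from flyforget.costs import expected_max_with_laplace_offset
        b = BeliefState(np.array([0.3, 0.45, 0.25]))
        q_ap = immediate_expected_reinforcement(b, env)
        expected = expected_max_with_laplace_offset(q_ap, 0.0, costs) - costs.scale
        got = provident_value(b, 1, DPConfig(horizon=1, gamma=0.9), env, costs)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_gamma_zero_reduces_to_greedy(self, env, costs, rng):
        cfg = DPConfig(horizon=5, gamma=0.0)
        p = ProvidentPolicy(cfg, env, costs)
        g = GreedyPolicy(env)
        for _ in range(1000):
            b = BeliefState(rng.dirichlet([1, 1, 1]))
            c_ap, c_av = rng.exponential(costs.scale, 2)
            assert p.decide(b, c_ap, c_av) == g.decide(b, c_ap, c_av)

    def test_value_matches_naive_quadrature_recursion(self, env, costs):
        """Scalar recursion with numeric cost integration, no closed forms."""
        P = build_transition_matrix(env)
        E = emission_matrix(env, "ap")
        w = reinforcement_weights(env)
        gamma = 0.95
        law = stats.laplace(scale=costs.scale)

        def naive_v(b, k):
            if k == 0:
                return 0.0
            qa = float(b @ w)
            for y in range(3):
                py = float(b @ E[:, y])
                if py > 0:
                    child = ((b * E[:, y]) / py) @ P
                    qa += gamma * py * naive_v(child, k - 1)
            qv = gamma * naive_v(b @ P, k - 1)
            kink = qa - qv
            cut = abs(kink) + 60.0 * costs.scale
            pieces = sorted({-cut, kink, 0.0, cut})
            emax, tot_err = 0.0, 0.0
            for lo_b, hi_b in zip(pieces, pieces[1:]):
                val, err = integrate.quad(
                    lambda d: max(qa, qv + d) * law.pdf(d), lo_b, hi_b,
                    limit=200, epsabs=1e-12, epsrel=1e-12)
                emax += val
                tot_err += err
            assert tot_err < 5e-9
            return emax - costs.scale

        rng = np.random.default_rng(42)
        for _ in range(3):
            b = rng.dirichlet([1, 1, 1])
            expected = naive_v(b, 3)
            got = provident_value(BeliefState(b), 3,
                                  DPConfig(horizon=3, gamma=gamma), env, costs)
            assert got == pytest.approx(expected, abs=1e-7)

    def test_value_matches_policy_rollout(self, env, costs):
        """Monte-Carlo rollouts following the finite-horizon DP policy must
        reproduce the DP value within sampling error."""
        gamma, K, n_ep = 0.95, 3, 200_000
        P = build_transition_matrix(env)
        E = {a: emission_matrix(env, a) for a in ("ap", "av")}
        values = np.array([env.reward_pos, 0.0, env.reward_neg])
        rng = np.random.default_rng(7)
        b0 = np.array([0.2, 0.5, 0.3])
        v_dp = provident_value(BeliefState(b0), K,
                               DPConfig(horizon=K, gamma=gamma), env, costs)
        states = rng.choice(3, size=n_ep, p=b0)
        beliefs = np.tile(b0, (n_ep, 1))
        total = np.zeros(n_ep)
        for t in range(K):
            cfg = DPConfig(horizon=K - t, gamma=gamma)
            theta = provident_thresholds(beliefs, cfg, env, costs)
            c_ap = rng.exponential(costs.scale, n_ep)
            c_av = rng.exponential(costs.scale, n_ep)
            ap = theta + (c_av - c_ap) >= 0
            # sample signals from the true state's emissions
            u = rng.random(n_ep)
            probs = np.where(ap[:, None], E["ap"][states], E["av"][states])
            y = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
            reward = np.where(ap, values[y], 0.0) - np.where(ap, c_ap, c_av)
            total += gamma ** t * reward
            # belief filtering, vectorized
            liks = np.where(ap[:, None],
                            E["ap"][:, y].T, E["av"][:, y].T)
            post = beliefs * liks
            post /= post.sum(axis=1, keepdims=True)
            beliefs = post @ P
            u2 = rng.random(n_ep)
            states = (u2[:, None] > P[states].cumsum(axis=1)).sum(axis=1)
        se = total.std() / np.sqrt(n_ep)
        assert abs(total.mean() - v_dp) < 3 * se

    def test_information_bonus_at_stationary(self, env, costs, dp_cfg):
        p = ProvidentPolicy(dp_cfg, env, costs)
        g = GreedyPolicy(env)
        pi = stationary_belief(env)
        assert p.threshold(pi) > g.threshold(pi)

    def test_threshold_monotone_in_reward_belief(self, env, costs, dp_cfg):
        # increasing b_r at fixed b_p must never flip approach to avoid
        p = ProvidentPolicy(dp_cfg, env, costs)
        for b_p in (0.0, 0.2, 0.4):
            b_rs = np.linspace(0.0, 1.0 - b_p, 21)
            B = np.stack([b_rs, 1 - b_rs - b_p, np.full_like(b_rs, b_p)],
                         axis=1)
            theta = p.thresholds(B)
            assert np.all(np.diff(theta) > -1e-9)

    def test_larger_avoid_cost_shrinks_avoid_region(self, env, costs, dp_cfg):
        p = ProvidentPolicy(dp_cfg, env, costs)
        B = _simplex_grid(20)
        theta = p.thresholds(B)
        for extra in (0.0, 0.2, 0.4):
            n_av_low = int(np.sum(theta + extra < 0))
            n_av_high = int(np.sum(theta + extra + 0.2 < 0))
            assert n_av_high <= n_av_low

    def test_depends_only_on_cost_difference(self, env, costs, dp_cfg, rng):
        p = ProvidentPolicy(dp_cfg, env, costs)
        for _ in range(50):
            b = BeliefState(rng.dirichlet([1, 1, 1]))
            c_ap, c_av = rng.exponential(costs.scale, 2)
            shift = rng.uniform(0, 3)
            assert p.decide(b, c_ap, c_av) == p.decide(b, c_ap + shift,
                                                       c_av + shift)


class TestBaselines:
    def test_pool_contents(self, env):
        pool = baseline_policies(env)
        assert set(pool) == {"no_forgetting", "immediate_forgetting",
                             "always_ap", "always_av"}

    def test_immediate_forgetting_symmetric_coin(self, env, costs, rng):
        pol = ImmediateForgettingPolicy()
        b = stationary_belief(env)
        n = 10 ** 5
        c_ap = rng.exponential(costs.scale, n)
        c_av = rng.exponential(costs.scale, n)
        frac_ap = np.mean([c1 <= c2 for c1, c2 in zip(c_ap, c_av)])
        decisions = np.array([pol.decide(b, c1, c2) == "ap"
                              for c1, c2 in zip(c_ap[:1000], c_av[:1000])])
        assert abs(frac_ap - 0.5) < 3 * 0.5 / np.sqrt(n)
        assert abs(decisions.mean() - 0.5) < 3 * 0.5 / np.sqrt(1000)

    def test_no_forgetting_belief_is_frozen_under_avoid(self, env):
        pol = NoForgettingPolicy(env)
        b = BeliefState(np.array([0.05, 0.15, 0.8]))
        assert pol.evolve(b, "av", "0", env) is b

    def test_constant_policies(self, env):
        b = stationary_belief(env)
        assert ConstantPolicy("ap").decide(b, 9.0, 0.0) == "ap"
        assert ConstantPolicy("av").decide(b, 0.0, 9.0) == "av"


class TestFreeRuns:
    def test_forced_avoid_in_zero_reinforcement_env(self, costs, rng):
        env0 = EnvParams(reward_pos=0.0, reward_neg=0.0)
        res = evaluate_total_reward(ConstantPolicy("av"), env0, costs,
                                    T=500, n_runs=20, rng=rng)
        # pays the avoid cost (mean = scale) every step
        expected = -costs.scale * 500
        assert abs(res.mean - expected) < 3 * res.sem

    def test_greedy_beats_memoryless_baselines(self, env, costs):
        from flyforget.policies import paired_policy_comparison
        pols = {"greedy": GreedyPolicy(env),
                "immediate_forgetting": ImmediateForgettingPolicy(),
                "no_forgetting": NoForgettingPolicy(env)}
        out = paired_policy_comparison(pols, env, costs, T=600, n_runs=25,
                                       seed=11)
        d_imm, se_imm = out["differences"][("greedy", "immediate_forgetting")]
        d_nf, se_nf = out["differences"][("greedy", "no_forgetting")]
        assert d_imm > 2 * se_imm
        assert d_nf > 2 * se_nf
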