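"""Policy contract, greedy policy, baselines and closed-loop evaluation.

Every policy maps (belief, sampled costs of responding) to an action in
``{"ap", "av"}``.  All policies in this package are measurable in the cost
*difference* ``c_av - c_ap`` only: most are threshold policies that approach
whenever ``threshold(belief) + (c_av - c_ap) >= 0``, which makes the
probability of approaching a Laplace CDF evaluated at the belief-dependent
threshold.  Ties are broken toward approach, the information-gathering action.
"""

from __future__ import annotations

import numpy as np

from ..belief import BeliefState, belief_update, likelihood_vector
from ..costs import CostModel
from ..environment import EnvParams

__all__ = ["Policy", "ThresholdPolicy", "GreedyPolicy", "NoForgettingPolicy",
           "ImmediateForgettingPolicy", "ConstantPolicy", "baseline_policies",
           "immediate_expected_reinforcement", "reinforcement_weights",
           "evaluate_total_reward", "FreeRunResult",
           "paired_policy_comparison"]


def reinforcement_weights(env: EnvParams) -> np.ndarray:
    """Per-state expected reinforcement of approaching: E[signal value | s, ap]."""
    return np.array([
        env.reward_pos,
        env.p_pos_emit_n * env.reward_pos + env.p_neg_emit_n * env.reward_neg,
        env.reward_neg,
    ])


def immediate_expected_reinforcement(b: BeliefState, env: EnvParams) -> float:
    """Expected reinforcement of one approach under belief ``b``.

    With symmetric spurious emissions and rewards +-1 this is simply
    ``b_r - b_p``.  Avoiding yields 0 by construction.
    """
    probs = b.probs if b.probs.shape[0] == 3 else b.probs[:3] + b.probs[3:]
    return float(probs @ reinforcement_weights(env))


class Policy:
    """Base contract: deterministic action given belief and sampled costs."""

    name: str = "policy"

    def decide(self, b: BeliefState, c_ap: float, c_av: float) -> str:
        raise NotImplementedError

    def evolve(self, b: BeliefState, action: str, signal: str,
               env) -> BeliefState:
        """How this agent's memory (belief) changes after one step.

        The default is the exact Bayes filter; baselines override this to
        freeze or discard the memory.
        """
        return belief_update(b, action, signal, env)

    def descriptor(self) -> dict:
        return {"name": self.name}


class ThresholdPolicy(Policy):
    """Policy of the form: approach iff threshold(b) + (c_av - c_ap) >= 0."""

    def threshold(self, b: BeliefState) -> float:
        raise NotImplementedError

    def decide(self, b: BeliefState, c_ap: float, c_av: float) -> str:
        return "ap" if self.threshold(b) + (c_av - c_ap) >= 0.0 else "av"

    def prob_approach(self, b: BeliefState, costs: CostModel) -> float:
        """Exact P(approach | b) over the Laplace cost difference."""
        return float(costs.diff_distribution().sf(-self.threshold(b)))


class GreedyPolicy(ThresholdPolicy):
    """Maximize immediate net reward: approach iff the expected reinforcement
    beats the cost difference.  Equivalent to the discounted-optimal policy at
    discount factor 0."""

    name = "greedy"

    def __init__(self, env: EnvParams):
        self.env = env

    def threshold(self, b: BeliefState) -> float:
        return immediate_expected_reinforcement(b, self.env)

    def descriptor(self) -> dict:
        return {"name": self.name, "env": self.env.to_dict()}


class NoForgettingPolicy(ThresholdPolicy):
    """Greedy agent whose memory never decays.

    The belief is corrected by informative signals but is never pushed through
    the transition matrix, so in the absence of new information it stays
    frozen at its post-conditioning value.
    """

    name = "no_forgetting"

    def __init__(self, env: EnvParams):
        self.env = env

    def threshold(self, b: BeliefState) -> float:
        return immediate_expected_reinforcement(b, self.env)

    def evolve(self, b: BeliefState, action: str, signal: str,
               env) -> BeliefState:
        if action == "av":
            return b
        lik = likelihood_vector(action, signal, self.env,
                                n_states=b.probs.shape[0])
        post = b.probs * lik
        total = post.sum()
        if total <= 0.0:
            raise ValueError("zero-likelihood observation")
        return BeliefState(post / total)


class ImmediateForgettingPolicy(ThresholdPolicy):
    """Memoryless agent: decides by the costs alone (threshold 0)."""

    name = "immediate_forgetting"

    def threshold(self, b: BeliefState) -> float:
        return 0.0


class ConstantPolicy(Policy):
    """Always take the same action, regardless of belief and costs."""

    def __init__(self, action: str):
        if action not in ("ap", "av"):
            raise ValueError("action must be 'ap' or 'av'")
        self.action = action
        self.name = f"always_{action}"

    def decide(self, b: BeliefState, c_ap: float, c_av: float) -> str:
        return self.action


def baseline_policies(env: EnvParams) -> dict[str, Policy]:
    """The reference policies against which forgetting is compared."""
    return {
        "no_forgetting": NoForgettingPolicy(env),
        "immediate_forgetting": ImmediateForgettingPolicy(),
        "always_ap": ConstantPolicy("ap"),
        "always_av": ConstantPolicy("av"),
    }


class FreeRunResult:
    """Total net reward of repeated free runs: mean, s.e.m. and raw totals."""

    def __init__(self, totals: np.ndarray, T: int):
        self.totals = np.asarray(totals, dtype=float)
        self.T = T

    @property
    def mean(self) -> float:
        return float(self.totals.mean())

    @property
    def sem(self) -> float:
        n = self.totals.size
        return float(self.totals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    @property
    def rate(self) -> float:
        """Average net reward per time bin."""
        return self.mean / self.T

    def __repr__(self) -> str:
        return f"FreeRunResult(mean={self.mean:.2f}, sem={self.sem:.2f}, T={self.T})"


def evaluate_total_reward(policy: Policy, env: EnvParams, costs: CostModel,
                          T: int, n_runs: int,
                          rng: np.random.Generator) -> FreeRunResult:
    """Closed-loop simulation of ``n_runs`` free runs of ``T`` time bins.

    The hidden state starts from the stationary distribution and the agent
    from the stationary belief.  Each bin: costs are drawn, the policy acts,
    the current state emits the reinforcement, the agent's memory evolves,
    then the state transitions.  Total = sum of reinforcement minus the cost
    of the chosen action.
    """
    from ..environment import (build_transition_matrix, emission_matrix,
                               stationary_distribution, SIGNALS)
    if T < 1:
        raise ValueError("T must be at least 1")
    P = build_transition_matrix(env)
    pi = stationary_distribution(P)
    emit = {a: emission_matrix(env, a) for a in ("ap", "av")}
    values = np.array([env.reward_pos, 0.0, env.reward_neg])  # for (+, 0, -)
    b0 = BeliefState(pi)
    totals = np.empty(n_runs)
    for run in range(n_runs):
        s = int(rng.choice(3, p=pi))
        b = b0
        total = 0.0
        for _ in range(T):
            c_ap = float(rng.exponential(costs.scale))
            c_av = float(rng.exponential(costs.scale))
            action = policy.decide(b, c_ap, c_av)
            y = int(rng.choice(3, p=emit[action][s]))
            total += values[y] - (c_ap if action == "ap" else c_av)
            b = policy.evolve(b, action, SIGNALS[y], env)
            s = int(rng.choice(3, p=P[s]))
        totals[run] = total
    return FreeRunResult(totals, T)


def paired_policy_comparison(policies: dict[str, Policy], env: EnvParams,
                             costs: CostModel, T: int, n_runs: int,
                             seed: int) -> dict:
    """Free-run comparison with common random numbers.

    Every policy is evaluated on the same ``n_runs`` seeded streams (one
    stream per run, shared across policies), so per-run totals are directly
    comparable and pairwise differences have far smaller standard errors than
    the between-run spread of either policy.  The environment does not react
    to the agent, and every step consumes the same number of random draws
    regardless of the action, so the hidden-state trajectory is identical
    across policies within a run.

    Returns per-policy FreeRunResult plus, for every policy pair, the mean
    paired difference and its s.e.m.
    """
    streams = np.random.SeedSequence(seed).spawn(n_runs)
    totals = {name: np.empty(n_runs) for name in policies}
    for i, ss in enumerate(streams):
        for name, pol in policies.items():
            rng = np.random.default_rng(
                np.random.SeedSequence(ss.entropy, spawn_key=ss.spawn_key))
            totals[name][i] = evaluate_total_reward(pol, env, costs, T, 1,
                                                    rng).totals[0]
    out = {"results": {n: FreeRunResult(t, T) for n, t in totals.items()},
           "differences": {}}
    names = list(policies)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = totals[a] - totals[b]
            out["differences"][(a, b)] = (
                float(d.mean()),
                float(d.std(ddof=1) / np.sqrt(n_runs)))
    return out
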