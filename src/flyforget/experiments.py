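"""Classical-conditioning protocols and forgetting curves.

A conditioning experiment is emulated as in the fly laboratory: the agent
experiences one or more defined environmental states (clamped observations,
updating the belief only — the environment is not co-simulated), waits for a
delay while the belief drifts toward stationarity, and is then tested once
with freshly drawn costs of responding.  The forgetting curve is the fraction
of agents emitting the conditioned response as a function of the delay.

Because the belief trajectory is deterministic given the protocol, every agent
at a given delay shares one belief and the curve is a binomial functional of
that trajectory; for threshold policies the exact fraction is the Laplace
cost-difference CDF at the decision threshold, used as the direct-computation
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .belief import BeliefState, stationary_belief, marginal_env_belief
from .costs import CostModel, sample_costs
from .environment import EnvParams, ExtEnvParams
from .policies import GreedyPolicy, Policy, ProvidentPolicy, ThresholdPolicy

__all__ = ["Protocol", "ForgettingCurve", "make_protocol", "forgetting_curve",
           "exact_forgetting_curve", "half_gap_delay", "asymmetry_experiment",
           "extended_forgetting", "retest_experiment",
           "PROTOCOL_NAMES", "default_delays"]

_EVENT_SIGNAL = {"appetitive": "+", "aversive": "-", "neutral": "0"}
_EVENT_CR = {"appetitive": "ap", "aversive": "av"}

PROTOCOL_NAMES = ("single_appetitive", "single_aversive", "spaced", "massed",
                  "reversal")


@dataclass(frozen=True)
class Protocol:
    """Ordered conditioning events at strictly increasing time bins."""

    name: str
    events: tuple  # of (time_bin, event)
    model: str = "basic"

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(t < 0 for t in times) or any(
                b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing and >= 0")
        for _, e in self.events:
            if e not in _EVENT_SIGNAL:
                raise ValueError(f"unknown event {e!r}")

    @property
    def conditioned_response(self) -> str:
        """Action matching the last non-neutral conditioning event."""
        for _, e in reversed(self.events):
            if e in _EVENT_CR:
                return _EVENT_CR[e]
        raise ValueError("protocol has no reinforcing event")


@dataclass(frozen=True)
class ForgettingCurve:
    """Fraction of agents emitting the conditioned response per delay."""

    delays: np.ndarray
    fraction_cr: np.ndarray
    stderr: np.ndarray
    n_agents: int
    conditioned_response: str
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("delays", "fraction_cr", "stderr"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (self.delays.shape == self.fraction_cr.shape == self.stderr.shape):
            raise ValueError("curve fields must share one grid")
        if np.any((self.fraction_cr < 0) | (self.fraction_cr > 1)):
            raise ValueError("fractions must lie in [0, 1]")


def make_protocol(name: str) -> Protocol:
    """Standard conditioning protocols.

    spaced:   six aversive conditionings separated by 9 waiting bins,
    massed:   six aversive conditionings in consecutive bins,
    reversal: aversive, neutral, aversive in consecutive bins,
    singles:  one appetitive or aversive conditioning.
    """
    if name == "single_appetitive":
        events = ((0, "appetitive"),)
    elif name == "single_aversive":
        events = ((0, "aversive"),)
    elif name == "spaced":
        events = tuple((10 * k, "aversive") for k in range(6))
    elif name == "massed":
        events = tuple((k, "aversive") for k in range(6))
    elif name == "reversal":
        events = ((0, "aversive"), (1, "neutral"), (2, "aversive"))
    else:
        raise ValueError(f"unknown protocol {name!r}")
    return Protocol(name=name, events=events)


def _post_training_belief(policy: Policy, protocol: Protocol,
                          env: EnvParams) -> BeliefState:
    """Belief right after the last conditioning event.

    Events consume one bin each; the belief drifts (avoid updates) through
    the waiting bins in between.
    """
    b = stationary_belief(env)
    prev_t = None
    for t, event in protocol.events:
        if prev_t is not None:
            for _ in range(t - prev_t - 1):
                b = policy.evolve(b, "av", "0", env)
        b = policy.evolve(b, "ap", _EVENT_SIGNAL[event], env)
        prev_t = t
    return b


def _fraction_mc(policy: Policy, b: BeliefState, cr: str, n_agents: int,
                 costs: CostModel, rng: np.random.Generator) -> float:
    if isinstance(policy, ThresholdPolicy):
        # one comparison per agent against the sampled cost difference
        theta = policy.threshold(b)
        c_ap, c_av = sample_costs(costs, rng, size=n_agents)
        chose_ap = theta + (c_av - c_ap) >= 0.0
        n_cr = int(np.sum(chose_ap if cr == "ap" else ~chose_ap))
    else:
        n_cr = 0
        for _ in range(n_agents):
            c_ap, c_av = sample_costs(costs, rng)
            if policy.decide(b, c_ap, c_av) == cr:
                n_cr += 1
    return n_cr / n_agents


def default_delays(max_delay: int = 200, n_points: int = 21) -> np.ndarray:
    """Roughly log-spaced integer delay grid from 0 to ``max_delay``."""
    grid = np.unique(np.round(
        np.geomspace(1.0, max_delay + 1, n_points) - 1.0).astype(int))
    return grid


def forgetting_curve(policy: Policy, protocol: Protocol, delays, n_agents: int,
                     env: EnvParams, costs: CostModel,
                     rng: np.random.Generator,
                     label: str = "") -> ForgettingCurve:
    """Monte-Carlo forgetting curve: each agent is tested once per delay with
    fresh costs; all agents share the protocol-determined belief."""
    if n_agents < 1:
        raise ValueError("n_agents must be at least 1")
    delays = np.asarray(sorted(int(d) for d in delays))
    cr = protocol.conditioned_response
    b = _post_training_belief(policy, protocol, env)
    fractions = np.empty(delays.size)
    cur = 0
    for i, d in enumerate(delays):
        while cur < d:
            b = policy.evolve(b, "av", "0", env)
            cur += 1
        fractions[i] = _fraction_mc(policy, b, cr, n_agents, costs, rng)
    stderr = np.sqrt(fractions * (1.0 - fractions) / n_agents)
    return ForgettingCurve(delays, fractions, stderr, n_agents, cr,
                           label or f"{policy.name}:{protocol.name}")


def exact_forgetting_curve(policy: ThresholdPolicy, protocol: Protocol,
                           delays, env: EnvParams,
                           costs: CostModel, label: str = "") -> ForgettingCurve:
    """Noise-free forgetting curve for threshold policies.

    The fraction at each delay is the exact Laplace cost-difference
    probability of the conditioned response at the shared belief.
    """
    delays = np.asarray(sorted(int(d) for d in delays))
    cr = protocol.conditioned_response
    b = _post_training_belief(policy, protocol, env)
    fractions = np.empty(delays.size)
    cur = 0
    for i, d in enumerate(delays):
        while cur < d:
            b = policy.evolve(b, "av", "0", env)
            cur += 1
        p_ap = policy.prob_approach(b, costs)
        fractions[i] = p_ap if cr == "ap" else 1.0 - p_ap
    return ForgettingCurve(delays, fractions, np.zeros_like(fractions),
                           1, cr, label or f"{policy.name}:{protocol.name}")


def half_gap_delay(curve: ForgettingCurve) -> float:
    """Delay at which the curve has covered half the gap between its initial
    value and its large-delay asymptote (last grid point), by linear
    interpolation; ``inf`` if the curve never reaches the midpoint."""
    f = curve.fraction_cr
    target = 0.5 * (f[0] + f[-1])
    toward_asymptote = f[0] > f[-1]
    for i in range(1, f.size):
        crossed = f[i] <= target if toward_asymptote else f[i] >= target
        if crossed:
            f0, f1 = f[i - 1], f[i]
            d0, d1 = curve.delays[i - 1], curve.delays[i]
            if f1 == f0:
                return float(d1)
            return float(d0 + (target - f0) * (d1 - d0) / (f1 - f0))
    return float("inf")


def asymmetry_experiment(env: EnvParams, costs: CostModel, dp_cfg, delays,
                         n_agents: int, rng: np.random.Generator,
                         policy: Policy | None = None):
    """Forgetting after appetitive vs aversive conditioning, same policy.

    With symmetric chain rates any asymmetry between the two curves comes from
    the policy alone.  Returns ((appetitive curve, aversive curve), summary
    dict with the half-gap delays).
    """
    if abs(env.a_rn - env.a_pn) > 1e-12:
        raise ValueError("asymmetry experiment requires symmetric chain rates")
    if policy is None:
        policy = ProvidentPolicy(dp_cfg, env, costs)
    curves = []
    for proto_name in ("single_appetitive", "single_aversive"):
        curves.append(forgetting_curve(policy, make_protocol(proto_name),
                                       delays, n_agents, env, costs, rng))
    summary = {
        "half_gap_appetitive": half_gap_delay(curves[0]),
        "half_gap_aversive": half_gap_delay(curves[1]),
        "policy": policy.name,
    }
    return (curves[0], curves[1]), summary


def _extended_schedule(name: str, refinement: int):
    """Conditioning events in extended time bins.

    Spaced waits are 9 *basic* bins (9 * refinement extended bins) so that the
    protocol matches the basic-model definition, while massed and reversal
    pack their events into consecutive extended bins — the point of the finer
    discretization is that massed/reversal pairings follow each other faster
    than one basic bin.
    """
    if name == "spaced":
        step = 9 * refinement + 1
        return tuple((step * k, "aversive") for k in range(6))
    if name == "massed":
        return tuple((k, "aversive") for k in range(6))
    if name == "reversal":
        return ((0, "aversive"), (1, "neutral"), (2, "aversive"))
    raise ValueError(f"unknown extended protocol {name!r}")


def extended_forgetting(ext_env: ExtEnvParams, costs: CostModel, delays,
                        n_agents: int, rng: np.random.Generator,
                        protocols=("spaced", "massed", "reversal")):
    """Spaced / massed / reversal training under the slow-fast meta model.

    Six-state filtering; decisions use the greedy policy on the marginal
    environmental belief.  Delays are in basic bins (each worth
    ``time_refinement`` extended bins).  Returns (curves dict, slow-mode
    posterior dict: P(slow | training) right after the last event).
    """
    greedy = GreedyPolicy(ext_env.base_slow)
    delays = np.asarray(sorted(int(d) for d in delays))
    refinement = ext_env.time_refinement
    curves: dict[str, ForgettingCurve] = {}
    p_slow: dict[str, float] = {}
    for name in protocols:
        proto = Protocol(name=name, events=_extended_schedule(name, refinement),
                         model="extended")
        b = _post_training_belief(greedy, proto, ext_env)
        p_slow[name] = float(b.probs[:3].sum())
        cr = proto.conditioned_response
        fractions = np.empty(delays.size)
        cur = 0
        for i, d in enumerate(delays):
            target = int(d) * refinement
            while cur < target:
                b = greedy.evolve(b, "av", "0", ext_env)
                cur += 1
            theta = greedy.threshold(marginal_env_belief(b))
            c_ap, c_av = sample_costs(costs, rng, size=n_agents)
            chose_ap = theta + (c_av - c_ap) >= 0.0
            n_cr = int(np.sum(chose_ap if cr == "ap" else ~chose_ap))
            fractions[i] = n_cr / n_agents
        stderr = np.sqrt(fractions * (1.0 - fractions) / n_agents)
        curves[name] = ForgettingCurve(delays, fractions, stderr, n_agents,
                                       cr, f"extended:{name}")
    return curves, p_slow


def retest_experiment(policy: Policy, b: BeliefState, n_agents: int,
                      costs: CostModel, rng: np.random.Generator, cr: str):
    """Test, regroup by first response, retest both groups at the same belief.

    Costs are redrawn independently at retest, so the conditioned-response
    fraction should be the same in both groups and equal to the first-test
    fraction.  Returns a dict with the three fractions and group sizes.
    """
    first = np.array([
        policy.decide(b, *sample_costs(costs, rng)) == cr
        for _ in range(n_agents)])
    retest = np.array([
        policy.decide(b, *sample_costs(costs, rng)) == cr
        for _ in range(n_agents)])
    n_yes = int(first.sum())
    n_no = n_agents - n_yes
    return {
        "first_fraction": n_yes / n_agents,
        "retest_fraction_cr_group": float(retest[first].mean()) if n_yes else np.nan,
        "retest_fraction_other_group": float(retest[~first].mean()) if n_no else np.nan,
        "n_cr_group": n_yes,
        "n_other_group": n_no,
    }
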