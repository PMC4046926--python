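"""Bayesian filtering of the hidden environmental state.

The belief is the posterior over the hidden state given the agent's past
actions and reinforcement signals; it is the sufficient statistic on which
every policy in this package operates.  One filter step is
*correct-then-predict*:

    b'(s') ∝ Σ_s b(s) · P(signal | s, action) · P(s' | s)

so that avoiding (which is uninformative) reduces exactly to one multiplication
by the transition matrix, and the stationary distribution is a fixed point of
the avoid update.  Forgetting, in this picture, is nothing but the drift of the
belief back toward that stationary point while no information arrives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import (EnvParams, ExtEnvParams, build_transition_matrix,
                          build_extended_chain, emission_matrix,
                          stationary_distribution, SIGNALS)

__all__ = ["BeliefState", "belief_update", "drift", "conditioned_belief",
           "stationary_belief", "likelihood_vector", "marginal_env_belief"]

_EVENT_SIGNAL = {"appetitive": "+", "aversive": "-", "neutral": "0"}


@dataclass(frozen=True)
class BeliefState:
    """Probability vector over hidden states (length 3 basic, 6 extended)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1 or p.shape[0] not in (3, 6):
            raise ValueError("belief must be a length-3 or length-6 vector")
        if np.any(p < -1e-12):
            raise ValueError("belief entries must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"belief entries sum to {p.sum()}, not 1")

    @property
    def b_r(self) -> float:
        return float(self.probs[0])

    @property
    def b_n(self) -> float:
        return float(self.probs[1])

    @property
    def b_p(self) -> float:
        return float(self.probs[2])

    def __iter__(self):
        return iter(self.probs)


def likelihood_vector(action: str, signal: str, env: EnvParams,
                      n_states: int = 3) -> np.ndarray:
    """P(signal | state, action) for every hidden state.

    For the 6-state extended space the emission depends only on the
    environmental component, so the 3-vector is tiled over the meta states.
    """
    lik = emission_matrix(env, action)[:, SIGNALS.index(signal)]
    if n_states == 6:
        lik = np.tile(lik, 2)
    return lik


def _transition(env: EnvParams | ExtEnvParams) -> np.ndarray:
    if isinstance(env, ExtEnvParams):
        return build_extended_chain(env)
    return build_transition_matrix(env)


def _emission_env(env: EnvParams | ExtEnvParams) -> EnvParams:
    # emissions of the extended model depend only on the env component
    return env.base_slow if isinstance(env, ExtEnvParams) else env


def belief_update(b: BeliefState, action: str, signal: str,
                  env: EnvParams | ExtEnvParams) -> BeliefState:
    """One Bayes-filter step: correct by the (action, signal) likelihood,
    then predict through the transition matrix.

    Raises ``ValueError`` if the observation has zero likelihood under ``b``
    (e.g. a reinforcement signal while avoiding).
    """
    n = b.probs.shape[0]
    lik = likelihood_vector(action, signal, _emission_env(env), n_states=n)
    post = b.probs * lik
    total = post.sum()
    if total <= 0.0:
        raise ValueError(
            f"observation (action={action!r}, signal={signal!r}) has zero "
            "likelihood under the current belief")
    return BeliefState((post / total) @ _transition(env))


def drift(b: BeliefState, k: int, env: EnvParams | ExtEnvParams) -> BeliefState:
    """Belief after ``k`` uninformative (avoid) steps: b P^k."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    P = _transition(env)
    return BeliefState(b.probs @ np.linalg.matrix_power(P, k))


def stationary_belief(env: EnvParams | ExtEnvParams) -> BeliefState:
    """The fixed point of the avoid update: the chain's stationary law."""
    return BeliefState(stationary_distribution(_transition(env)))


def conditioned_belief(event: str, env: EnvParams | ExtEnvParams,
                       b0: BeliefState | None = None) -> BeliefState:
    """Belief after one conditioning event (clamped observation).

    Conditioning is modelled as experiencing a defined environmental state:
    one approach update with the signal implied by the event (+ for
    appetitive, - for aversive, 0 for neutral), starting from ``b0``
    (stationary by default).
    """
    if event not in _EVENT_SIGNAL:
        raise ValueError(f"unknown conditioning event {event!r}")
    if b0 is None:
        b0 = stationary_belief(env)
    return belief_update(b0, "ap", _EVENT_SIGNAL[event], env)


def marginal_env_belief(b: BeliefState) -> BeliefState:
    """Marginalize a 6-state extended belief over the meta variable."""
    if b.probs.shape[0] != 6:
        raise ValueError("expected a 6-state extended belief")
    return BeliefState(b.probs[:3] + b.probs[3:])
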