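"""Provident policy by finite-horizon dynamic programming.

The provident agent maximizes discounted future reward, which for discount
factors near 1 approximates the long-run reward rate.  Values are built by the
recursion

    V_k(b) = E_{c_ap, c_av} [ max( Q_ap^k(b) - c_ap,  Q_av^k(b) - c_av ) ]

with

    Q_ap^k(b) = R_ap(b) + gamma * sum_y P(y | b, ap) V_{k-1}(tau(b, ap, y))
    Q_av^k(b) =            gamma *                 V_{k-1}(tau(b, av, 0))

and V_0 = 0.  The expectation over the i.i.d. exponential costs is taken
analytically: writing D = c_ap - c_av (Laplace distributed),

    E[max(Q_ap - c_ap, Q_av - c_av)] = E[max(Q_ap, Q_av + D)] - E[c_ap],

exact by linearity, so each level costs one closed-form Laplace-max and one
constant mean-cost offset.  The expansion tree has 4 children per node (three
approach outcomes plus the single avoid outcome), hence 4^K leaves; the
recursion is evaluated level-wise on arrays so batches of beliefs share the
same pass.  Horizons beyond 7 are refused rather than silently slow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..belief import BeliefState
from ..costs import CostModel, expected_max_with_laplace_offset
from ..environment import EnvParams, build_transition_matrix, emission_matrix
from .base import ThresholdPolicy, reinforcement_weights

__all__ = ["DPConfig", "ProvidentPolicy", "provident_value",
           "provident_thresholds"]

_MAX_HORIZON = 7


@dataclass(frozen=True)
class DPConfig:
    """Horizon (number of value-iteration levels) and discount factor."""

    horizon: int = 5
    gamma: float = 0.95

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be at least 1")
        if self.horizon > _MAX_HORIZON:
            raise ValueError(
                f"horizon {self.horizon} refused: the expansion tree grows as "
                f"4^K; at most {_MAX_HORIZON} is supported")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")


def _expand_levels(B0: np.ndarray, K: int, P: np.ndarray, E: np.ndarray):
    """Forward pass: belief arrays and approach-outcome weights per level.

    Children of a node are ordered (ap,+), (ap,0), (ap,-), (av,0).  Outcomes
    with zero probability get a uniform placeholder belief and weight 0.
    """
    levels = [B0]
    weights = []  # P(y | b, ap), per level, shape (M, 3)
    B = B0
    for _ in range(K - 1):
        M = B.shape[0]
        py = B @ E                       # (M, 3) signal probabilities under ap
        post = B[:, :, None] * E[None, :, :]   # (M, state, signal)
        post = np.transpose(post, (0, 2, 1))   # (M, signal, state)
        safe = np.where(py[:, :, None] > 0.0, post / np.maximum(py, 1e-300)[:, :, None],
                        1.0 / 3.0)
        children = np.empty((M, 4, 3))
        children[:, :3, :] = safe @ P
        children[:, 3, :] = B @ P
        weights.append(py)
        B = children.reshape(M * 4, 3)
        levels.append(B)
    return levels, weights


def _backward(levels, weights, K: int, gamma: float, w_ap: np.ndarray,
              costs: CostModel):
    """Backward pass; returns (Q_ap, Q_av, V) arrays at the root level."""
    s = costs.scale
    B = levels[K - 1]
    Q_ap = B @ w_ap
    Q_av = np.zeros_like(Q_ap)
    for d in range(K - 2, -1, -1):
        V_child = (expected_max_with_laplace_offset(Q_ap, Q_av, costs) - s)
        V_child = V_child.reshape(-1, 4)
        B = levels[d]
        py = weights[d]
        Q_ap = B @ w_ap + gamma * np.einsum("my,my->m", py, V_child[:, :3])
        Q_av = gamma * V_child[:, 3]
    V = expected_max_with_laplace_offset(Q_ap, Q_av, costs) - s
    return Q_ap, Q_av, np.asarray(V)


def _root_quantities(beliefs: np.ndarray, cfg: DPConfig, env: EnvParams,
                     costs: CostModel):
    beliefs = np.atleast_2d(np.asarray(beliefs, dtype=float))
    P = build_transition_matrix(env)
    E = emission_matrix(env, "ap")       # (state, signal)
    w_ap = reinforcement_weights(env)
    levels, weights = _expand_levels(beliefs, cfg.horizon, P, E)
    return _backward(levels, weights, cfg.horizon, cfg.gamma, w_ap, costs)


def provident_thresholds(beliefs, cfg: DPConfig, env: EnvParams,
                         costs: CostModel) -> np.ndarray:
    """Decision thresholds Q_ap - Q_av for a batch of beliefs (N, 3).

    The agent approaches whenever ``threshold + (c_av - c_ap) >= 0``.
    """
    Q_ap, Q_av, _ = _root_quantities(beliefs, cfg, env, costs)
    return Q_ap - Q_av


def provident_value(b: BeliefState, k: int, cfg: DPConfig, env: EnvParams,
                    costs: CostModel) -> float:
    """Optimal expected discounted return over ``k`` steps from belief ``b``."""
    cfg_k = DPConfig(horizon=k, gamma=cfg.gamma)
    _, _, V = _root_quantities(b.probs[None, :], cfg_k, env, costs)
    return float(V[0])


class ProvidentPolicy(ThresholdPolicy):
    """Reward-rate-seeking policy: horizon-K discounted DP with analytic cost
    integration.  Thresholds are cached per belief so that the per-trial
    decision is a single comparison against the sampled cost difference."""

    name = "provident"

    def __init__(self, cfg: DPConfig, env: EnvParams, costs: CostModel):
        self.cfg = cfg
        self.env = env
        self.costs = costs
        self._cache: dict[bytes, float] = {}

    def threshold(self, b: BeliefState) -> float:
        key = b.probs.tobytes()
        theta = self._cache.get(key)
        if theta is None:
            theta = float(provident_thresholds(b.probs[None, :], self.cfg,
                                               self.env, self.costs)[0])
            self._cache[key] = theta
        return theta

    def thresholds(self, beliefs: np.ndarray) -> np.ndarray:
        """Vectorized thresholds for an (N, 3) belief array."""
        return provident_thresholds(beliefs, self.cfg, self.env, self.costs)

    def descriptor(self) -> dict:
        return {"name": self.name, "horizon": self.cfg.horizon,
                "gamma": self.cfg.gamma, "env": self.env.to_dict(),
                "cost_scale": self.costs.scale}
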