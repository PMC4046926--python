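"""Hidden Markov environment of a conditioned stimulus.

The stimulus (an odor, say) is associated with one of three hidden states:
rewarding ``r``, neutral ``n`` or punishing ``p``.  The state evolves as a
discrete-time Markov chain with small per-step transition probabilities; direct
``r <-> p`` jumps are excluded, so the association always relaxes through the
neutral state.  Approaching the stimulus reveals (noisy) information about the
state through a reinforcement signal, avoiding reveals nothing.

An extended variant adds a hidden two-state meta variable (slow / fast) that
selects between two sets of transition rates, modelling an environment whose
volatility itself changes over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

__all__ = [
    "STATES",
    "EXT_STATES",
    "SIGNALS",
    "EnvParams",
    "EnvReparam",
    "ExtEnvParams",
    "build_transition_matrix",
    "stationary_distribution",
    "reparam_to_rates",
    "emission_matrix",
    "emit_reinforcement",
    "signal_value",
    "sample_trajectory",
    "build_extended_chain",
]

#: order of the basic hidden states everywhere in this package
STATES = ("r", "n", "p")
#: extended state space: (env state, meta state), meta-major order slow, fast
EXT_STATES = tuple((s, m) for m in ("slow", "fast") for s in STATES)
#: reinforcement signals
SIGNALS = ("+", "0", "-")

_SCHEMA = "flyforget-env-v1"


@dataclass(frozen=True)
class EnvParams:
    """Transition rates and reinforcement model of the basic 3-state chain.

    Rates are per-time-bin transition probabilities.  ``a_rn`` is the
    probability of leaving the rewarding state for the neutral one, etc.;
    ``r -> p`` and ``p -> r`` are identically zero.  In the neutral state an
    approach yields the neutral signal with probability ``p_neutral_emit`` and
    spurious positive/negative signals with the remaining mass.
    """

    a_rn: float = 0.05
    a_nr: float = 0.005
    a_np: float = 0.005
    a_pn: float = 0.05
    reward_pos: float = 1.0
    reward_neg: float = -1.0
    p_neutral_emit: float = 0.99
    p_pos_emit_n: float = 0.005
    p_neg_emit_n: float = 0.005

    def __post_init__(self) -> None:
        for name in ("a_rn", "a_nr", "a_np", "a_pn",
                     "p_neutral_emit", "p_pos_emit_n", "p_neg_emit_n"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.a_nr + self.a_np > 1.0 + 1e-12:
            raise ValueError("a_nr + a_np exceeds 1")
        total = self.p_neutral_emit + self.p_pos_emit_n + self.p_neg_emit_n
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"neutral-state emission probabilities sum to {total}, not 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema"] = _SCHEMA
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnvParams":
        d = {k: v for k, v in d.items() if k != "schema"}
        return cls(**d)


@dataclass(frozen=True)
class EnvReparam:
    """(p_n, rho, timescale) re-parametrization of the basic chain.

    ``p_n`` is the stationary probability of the neutral state, ``rho`` the
    average reward per approach at stationarity
    (``reward_pos * pi_r + reward_neg * pi_p``) and ``timescale_rate`` the
    per-step probability of leaving a conditioned (r or p) state, whose inverse
    is the mean dwell time that sets the forgetting speed.
    """

    p_n: float
    rho: float
    timescale_rate: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_n < 1.0:
            raise ValueError("p_n must lie strictly inside (0, 1)")
        if not 0.0 < self.timescale_rate <= 1.0:
            raise ValueError("timescale_rate must lie in (0, 1]")


@dataclass(frozen=True)
class ExtEnvParams:
    """Six-state extended chain: basic rates gated by a slow/fast meta state.

    ``time_refinement`` extended bins correspond to one basic time bin; rates
    here are per *extended* bin.  Meta transitions (``q_sf``, ``q_fs``) are
    slow compared to the environmental rates they modulate.
    """

    base_slow: EnvParams = field(
        default_factory=lambda: EnvParams(a_rn=0.005, a_nr=0.0005,
                                          a_np=0.0005, a_pn=0.005))
    base_fast: EnvParams = field(
        default_factory=lambda: EnvParams(a_rn=0.05, a_nr=0.005,
                                          a_np=0.005, a_pn=0.05))
    q_sf: float = 0.001
    q_fs: float = 0.001
    time_refinement: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_sf <= 1.0 and 0.0 <= self.q_fs <= 1.0):
            raise ValueError("meta transition rates must lie in [0, 1]")
        if self.time_refinement < 1:
            raise ValueError("time_refinement must be a positive integer")

    def to_dict(self) -> dict:
        return {
            "schema": _SCHEMA,
            "base_slow": self.base_slow.to_dict(),
            "base_fast": self.base_fast.to_dict(),
            "q_sf": self.q_sf,
            "q_fs": self.q_fs,
            "time_refinement": self.time_refinement,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtEnvParams":
        return cls(
            base_slow=EnvParams.from_dict(d["base_slow"]),
            base_fast=EnvParams.from_dict(d["base_fast"]),
            q_sf=d["q_sf"], q_fs=d["q_fs"],
            time_refinement=d["time_refinement"],
        )


def build_transition_matrix(params: EnvParams) -> np.ndarray:
    """Row-stochastic 3x3 transition matrix over (r, n, p)."""
    if params.a_rn > 1.0 or params.a_pn > 1.0:
        raise ValueError("leaving rates exceed 1")
    P = np.array([
        [1.0 - params.a_rn, params.a_rn, 0.0],
        [params.a_nr, 1.0 - params.a_nr - params.a_np, params.a_np],
        [0.0, params.a_pn, 1.0 - params.a_pn],
    ])
    if np.any(P < -1e-15):
        raise ValueError("off-diagonal rates of some row sum beyond 1")
    return np.clip(P, 0.0, 1.0)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi P = pi.

    Raises ``ValueError`` for chains that are not irreducible (the stationary
    distribution would not be unique).
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if P.shape != (n, n):
        raise ValueError("transition matrix must be square")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("rows must sum to 1")
    n_comp, _ = connected_components(csr_matrix(P > 0), directed=True,
                                     connection="strong")
    if n_comp != 1:
        raise ValueError("chain is reducible; stationary distribution not unique")
    # solve pi (P - I) = 0 with the normalization row appended
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def reparam_to_rates(rep: EnvReparam, reward_pos: float = 1.0,
                     reward_neg: float = -1.0,
                     a_rn: float | None = None) -> EnvParams:
    """Recover transition rates from the (p_n, rho, timescale) description.

    The target stationary distribution is solved from ``pi_n = p_n`` and
    ``reward_pos * pi_r + reward_neg * pi_p = rho``.  Three constraints leave
    one free rate; by default the symmetric convention
    ``a_rn = a_pn = timescale_rate`` is used, and passing ``a_rn`` overrides
    the rewarding-state leaving rate (``a_pn`` then absorbs the timescale).
    The neutral-state entering rates follow from detailed balance, which holds
    exactly for this r-n-p chain.
    """
    denom = reward_pos - reward_neg
    if denom <= 0:
        raise ValueError("reward_pos must exceed reward_neg")
    pi_n = rep.p_n
    # pi_r + pi_p = 1 - p_n and reward_pos*pi_r + reward_neg*pi_p = rho
    pi_r = (rep.rho - reward_neg * (1.0 - pi_n)) / denom
    pi_p = 1.0 - pi_n - pi_r
    if pi_r < -1e-12 or pi_p < -1e-12:
        raise ValueError(
            f"(p_n={pi_n}, rho={rep.rho}) infeasible: implied stationary "
            f"probabilities pi_r={pi_r:.4g}, pi_p={pi_p:.4g} are negative")
    pi_r, pi_p = max(pi_r, 0.0), max(pi_p, 0.0)
    rate_r = rep.timescale_rate if a_rn is None else a_rn
    rate_p = rep.timescale_rate
    a_nr = pi_r * rate_r / pi_n
    a_np = pi_p * rate_p / pi_n
    if a_nr + a_np > 1.0:
        raise ValueError("implied neutral-state leaving rates exceed 1; "
                         "reduce timescale_rate or increase p_n")
    return EnvParams(a_rn=rate_r, a_nr=a_nr, a_np=a_np, a_pn=rate_p,
                     reward_pos=reward_pos, reward_neg=reward_neg)


def emission_matrix(params: EnvParams, action: str) -> np.ndarray:
    """P(signal | state, action) as a (3 states x 3 signals) matrix.

    Signals ordered (+, 0, -).  Avoiding always yields the neutral signal;
    approaching reveals the state deterministically in r and p and noisily
    (0.005 / 0.99 / 0.005 by default) in n.
    """
    if action == "av":
        return np.tile(np.array([0.0, 1.0, 0.0]), (3, 1))
    if action == "ap":
        return np.array([
            [1.0, 0.0, 0.0],
            [params.p_pos_emit_n, params.p_neutral_emit, params.p_neg_emit_n],
            [0.0, 0.0, 1.0],
        ])
    raise ValueError(f"unknown action {action!r}")


def emit_reinforcement(state: str, action: str, rng: np.random.Generator,
                       params: EnvParams | None = None,
                       size: int | None = None):
    """Sample the reinforcement signal for taking ``action`` in ``state``.

    Returns a single signal string, or an array of signals when ``size`` is
    given.
    """
    params = params or EnvParams()
    probs = emission_matrix(params, action)[STATES.index(state)]
    signals = np.array(SIGNALS)
    if size is None:
        return str(rng.choice(signals, p=probs))
    return rng.choice(signals, p=probs, size=size)


def signal_value(signal: str, params: EnvParams) -> float:
    """Reinforcement magnitude carried by a signal."""
    return {"+": params.reward_pos, "0": 0.0, "-": params.reward_neg}[signal]


def sample_trajectory(params: EnvParams, T: int, s0: str,
                      rng: np.random.Generator) -> list[str]:
    """Length-``T`` state sequence starting from ``s0`` (s0 is the first entry)."""
    if T < 0:
        raise ValueError("T must be nonnegative")
    P = build_transition_matrix(params)
    idx = STATES.index(s0)
    out = []
    for _ in range(T):
        out.append(STATES[idx])
        idx = rng.choice(3, p=P[idx])
    return out


def build_extended_chain(params: ExtEnvParams) -> np.ndarray:
    """Row-stochastic 6x6 matrix over (r,n,p) x (slow,fast).

    Within one extended bin the environmental transition (with rates picked by
    the current meta state) and the meta transition are independent, so the
    joint kernel is the product of the two conditionals.
    """
    P_slow = build_transition_matrix(params.base_slow)
    P_fast = build_transition_matrix(params.base_fast)
    Q = np.array([[1.0 - params.q_sf, params.q_sf],
                  [params.q_fs, 1.0 - params.q_fs]])
    P = np.zeros((6, 6))
    # state ordering: (r,slow),(n,slow),(p,slow),(r,fast),(n,fast),(p,fast)
    P[:3, :3] = Q[0, 0] * P_slow
    P[:3, 3:] = Q[0, 1] * P_slow
    P[3:, :3] = Q[1, 0] * P_fast
    P[3:, 3:] = Q[1, 1] * P_fast
    return P
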