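"""A simple mechanistic approximation of the belief-based agent.

Two synaptic strengths, w_ap and w_av, connect an odor-detecting neuron to
"approach" and "avoid" action neurons.  In the absence of feedback each
strength relaxes exponentially toward its baseline at its own rate,

    w <- w + alpha * (w_base - w),

and feedback resets them in a Hebbian / anti-Hebbian fashion: reward sets
w_ap to its maximum and w_av to zero, punishment the reverse.  The decision is
approach iff  w_ap - w_av + noise > 0, with the noise drawn from the same
Laplace law as the cost difference of the belief-based agents, so both agent
families face identical decision stochasticity.  Forgetting appears as the
relaxation of the strengths; a faster avoid-channel decay (alpha_av >
alpha_ap) mimics the provident policy's faster forgetting of aversive
memories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["MechParams", "MechState", "mech_update", "mech_decide",
           "mech_forgetting_fraction", "fit_mech_params", "MechFitResult"]


@dataclass(frozen=True)
class MechParams:
    """Decay rates, baselines, reset maxima and decision-noise scale."""

    alpha_ap: float = 0.05
    alpha_av: float = 0.05
    w_base_ap: float = 0.0
    w_base_av: float = 0.0
    w_max_ap: float = 1.0
    w_max_av: float = 1.0
    noise_scale: float = 0.3

    def __post_init__(self) -> None:
        for name in ("alpha_ap", "alpha_av"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for ch in ("ap", "av"):
            base = getattr(self, f"w_base_{ch}")
            w_max = getattr(self, f"w_max_{ch}")
            if not 0.0 <= base <= w_max:
                raise ValueError(f"need 0 <= w_base_{ch} <= w_max_{ch}")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")


@dataclass(frozen=True)
class MechState:
    """Current synaptic strengths."""

    w_ap: float
    w_av: float


def mech_update(state: MechState, event: str, params: MechParams) -> MechState:
    """One time bin: relax toward baseline, or reset on reinforcement."""
    if event == "none":
        return MechState(
            w_ap=state.w_ap + params.alpha_ap * (params.w_base_ap - state.w_ap),
            w_av=state.w_av + params.alpha_av * (params.w_base_av - state.w_av),
        )
    if event == "reward":
        return MechState(w_ap=params.w_max_ap, w_av=0.0)
    if event == "punishment":
        return MechState(w_ap=0.0, w_av=params.w_max_av)
    raise ValueError(f"unknown event {event!r}")


def mech_decide(state: MechState, noise_draw: float) -> str:
    """Approach iff w_ap - w_av + noise > 0."""
    return "ap" if state.w_ap - state.w_av + noise_draw > 0.0 else "av"


def _strengths_at_delays(event: str, delays: np.ndarray, params: MechParams):
    """Closed-form (w_ap, w_av) after the reset and ``delay`` silent bins."""
    if event == "reward":
        start = MechState(params.w_max_ap, 0.0)
    elif event == "punishment":
        start = MechState(0.0, params.w_max_av)
    else:
        raise ValueError(f"unknown conditioning event {event!r}")
    d = np.asarray(delays, dtype=float)
    w_ap = params.w_base_ap + (start.w_ap - params.w_base_ap) * (1.0 - params.alpha_ap) ** d
    w_av = params.w_base_av + (start.w_av - params.w_base_av) * (1.0 - params.alpha_av) ** d
    return w_ap, w_av


def mech_forgetting_fraction(event: str, delays, params: MechParams) -> np.ndarray:
    """Exact probability of the conditioned response at each delay.

    After reward conditioning the conditioned response is approach, after
    punishment it is avoid; the probability is the Laplace noise CDF of the
    strength difference.
    """
    w_ap, w_av = _strengths_at_delays(event, np.asarray(delays), params)
    p_ap = stats.laplace.sf(-(w_ap - w_av), loc=0.0, scale=params.noise_scale)
    return p_ap if event == "reward" else 1.0 - p_ap


class MechFitResult:
    """Fitted parameters plus fit diagnostics."""

    def __init__(self, params: MechParams, rmse: float, converged: bool,
                 n_restarts: int):
        self.params = params
        self.rmse = rmse
        self.converged = converged
        self.n_restarts = n_restarts

    def __repr__(self) -> str:
        return (f"MechFitResult(rmse={self.rmse:.4f}, "
                f"converged={self.converged}, params={self.params})")


def fit_mech_params(delays, target_appetitive, target_aversive,
                    mode: str = "provident", noise_scale: float = 0.3,
                    n_restarts: int = 10, seed: int = 0) -> MechFitResult:
    """Least-squares fit of the mechanistic forgetting curves to targets.

    ``target_appetitive`` / ``target_aversive`` are conditioned-response
    fractions on the common ``delays`` grid (after reward and punishment
    conditioning respectively).  ``mode='greedy'`` constrains the two decay
    rates to be equal; ``mode='provident'`` lets them differ.  The noise scale
    is held fixed so that the decision stochasticity matches the belief-based
    agents.  Bounded Nelder-Mead from ``n_restarts`` seeded random starts.
    """
    delays = np.asarray(delays, dtype=float)
    t_ap = np.asarray(target_appetitive, dtype=float)
    t_av = np.asarray(target_aversive, dtype=float)
    if not (delays.shape == t_ap.shape == t_av.shape):
        raise ValueError("delays and target curves must share one grid")
    if mode not in ("provident", "greedy"):
        raise ValueError("mode must be 'provident' or 'greedy'")
    shared_alpha = mode == "greedy"

    def unpack(x) -> MechParams:
        if shared_alpha:
            a_ap = a_av = x[0]
            rest = x[1:]
        else:
            a_ap, a_av = x[0], x[1]
            rest = x[2:]
        base_ap, base_av, max_ap, max_av = rest
        return MechParams(alpha_ap=a_ap, alpha_av=a_av,
                          w_base_ap=base_ap, w_base_av=base_av,
                          w_max_ap=max(max_ap, base_ap),
                          w_max_av=max(max_av, base_av),
                          noise_scale=noise_scale)

    def residual_vector(x) -> np.ndarray:
        p = unpack(x)
        pred_ap = mech_forgetting_fraction("reward", delays, p)
        pred_av = mech_forgetting_fraction("punishment", delays, p)
        return np.concatenate([pred_ap - t_ap, pred_av - t_av])

    def residuals(x) -> float:
        return float(np.sum(residual_vector(x) ** 2))

    n_alpha = 1 if shared_alpha else 2
    lo = np.array([1e-4] * n_alpha + [0.0, 0.0, 1e-3, 1e-3])
    hi = np.array([1.0] * n_alpha + [2.0, 2.0, 5.0, 5.0])
    rng = np.random.default_rng(seed)
    # structured starts covering both decay orderings guard against the
    # near-degenerate basin in which the rise of one channel mimics the
    # decay of the other; random restarts explore the rest
    if shared_alpha:
        structured = [np.array([a, 0.2, 0.2, 1.0, 1.0])
                      for a in (0.02, 0.05, 0.1)]
    else:
        structured = [np.array([a1, a2, 0.2, 0.2, 1.0, 1.0])
                      for a1, a2 in ((0.02, 0.08), (0.08, 0.02),
                                     (0.05, 0.05))]
    starts = structured + [lo + rng.random(lo.size) * (hi - lo)
                           for _ in range(n_restarts)]
    x_best, f_best, converged = None, np.inf, False
    for x0 in starts:
        res = optimize.minimize(residuals, x0, method="Nelder-Mead",
                                bounds=list(zip(lo, hi)),
                                options={"maxiter": 4000, "xatol": 1e-8,
                                         "fatol": 1e-12})
        # polish each basin with bounded least squares
        polish = optimize.least_squares(residual_vector,
                                        np.clip(res.x, lo, hi),
                                        bounds=(lo, hi), xtol=1e-12,
                                        ftol=1e-12)
        cand_f = polish.cost * 2
        cand_x, cand_ok = polish.x, bool(polish.success or res.success)
        if res.fun < cand_f:
            cand_f, cand_x, cand_ok = res.fun, res.x, bool(res.success)
        if cand_f < f_best:
            x_best, f_best, converged = cand_x, cand_f, cand_ok
    rmse = float(np.sqrt(f_best / (2 * delays.size)))
    return MechFitResult(unpack(x_best), rmse, converged, n_restarts)
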