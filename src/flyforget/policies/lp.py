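"""Reward-rate maximization by linear programming on a quantized space.

The belief simplex is quantized on a square lattice in the (b_r, b_p)
coordinates and the real line of cost differences ``delta = c_av - c_ap``
(Laplace distributed) is cut into intervals of equal probability mass.  On the
finite MDP over (lattice belief, cost bin) pairs the standard average-reward
occupation-measure linear program is solved:

    max  sum_{s,a} x(s,a) r(s,a)
    s.t. sum_a x(s,a) = sum_{s',a} x(s',a) P(s | s', a),   sum x = 1,  x >= 0.

Updated beliefs that fall off the lattice are assigned stochastically to the
vertices of the enclosing lattice triangle with barycentric weights, so the
expected rounded belief equals the exact belief.  The cost bin is redrawn
i.i.d. every step; per-bin rewards use the conditional mean cost of each
action given the bin, available in closed form because ``c_ap | delta`` is a
shifted exponential:  E[c_ap | delta] = max(0, -delta) + s/2  and
E[c_av | delta] = max(0, delta) + s/2.

The deterministic policy is read off the LP duals (the bias function h): the
optimal action maximizes r(s,a) + sum_s' P(s'|s,a) h(s').
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import laplace

from ..belief import BeliefState
from ..costs import CostModel
from ..environment import EnvParams, build_transition_matrix, emission_matrix
from .base import Policy, reinforcement_weights

__all__ = ["LPConfig", "LPPolicy", "lp_reward_rate_policy",
           "cost_bin_edges", "conditional_mean_costs",
           "relative_value_iteration"]


@dataclass(frozen=True)
class LPConfig:
    """Quantization resolution of the belief simplex and the cost line."""

    lattice_spacing: float = 1.0 / 20.0
    n_cost_bins: int = 11

    def __post_init__(self) -> None:
        m = 1.0 / self.lattice_spacing
        if abs(m - round(m)) > 1e-9:
            raise ValueError("lattice_spacing must divide 1")
        if self.n_cost_bins < 3 or self.n_cost_bins % 2 == 0:
            raise ValueError("n_cost_bins must be odd and at least 3")

    @property
    def m(self) -> int:
        """Number of lattice intervals per simplex edge."""
        return round(1.0 / self.lattice_spacing)


# ---------------------------------------------------------------------------
# lattice geometry (coordinates: u = b_r * m, v = b_p * m, u + v <= m)

def lattice_points(m: int) -> np.ndarray:
    """(n_g, 2) integer (i, j) lattice points of the simplex i + j <= m."""
    pts = [(i, j) for i in range(m + 1) for j in range(m + 1 - i)]
    return np.array(pts, dtype=int)


def lattice_index_map(m: int) -> dict[tuple[int, int], int]:
    return {tuple(p): k for k, p in enumerate(lattice_points(m))}


def lattice_beliefs(m: int) -> np.ndarray:
    """(n_g, 3) belief vectors (b_r, b_n, b_p) of the lattice points."""
    pts = lattice_points(m)
    b_r = pts[:, 0] / m
    b_p = pts[:, 1] / m
    return np.stack([b_r, 1.0 - b_r - b_p, b_p], axis=1)


def barycentric_round(b: np.ndarray, m: int):
    """Vertices and weights of the lattice triangle enclosing belief ``b``.

    Returns (vertices (3, 2) int array, weights (3,)); weights are
    barycentric, so the expected rounded belief equals ``b`` exactly.
    """
    u = b[0] * m
    v = b[2] * m
    i0 = int(min(np.floor(u), m - 1)) if u > 0 else 0
    j0 = int(min(np.floor(v), m - 1)) if v > 0 else 0
    fu, fv = u - i0, v - j0
    if fu + fv <= 1.0 + 1e-12:
        verts = np.array([(i0, j0), (i0 + 1, j0), (i0, j0 + 1)])
        w = np.array([1.0 - fu - fv, fu, fv])
    else:
        verts = np.array([(i0 + 1, j0 + 1), (i0, j0 + 1), (i0 + 1, j0)])
        w = np.array([fu + fv - 1.0, 1.0 - fu, 1.0 - fv])
    w = np.clip(w, 0.0, None)
    return verts, w / w.sum()


def nearest_lattice_index(b: np.ndarray, m: int,
                          index_map: dict) -> int:
    """Deterministic rounding for decision lookup: heaviest triangle vertex."""
    verts, w = barycentric_round(b, m)
    order = np.argsort(-w)
    for k in order:
        key = (int(verts[k, 0]), int(verts[k, 1]))
        if key in index_map:
            return index_map[key]
    raise RuntimeError("no valid lattice vertex found")  # pragma: no cover


# ---------------------------------------------------------------------------
# cost-difference bins

def cost_bin_edges(model: CostModel, n_bins: int) -> np.ndarray:
    """Equal-mass interval edges of the Laplace(0, scale) cost difference."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    return laplace.ppf(qs, loc=0.0, scale=model.scale)


def _neg_part_mass_integral(l: float, u: float, s: float) -> float:
    """integral of (-x) * laplace density over [l, u] ∩ (-inf, 0]."""
    hi = min(u, 0.0)
    if l >= 0.0 or hi <= l:
        return 0.0
    F = lambda x: -0.5 * np.exp(x / s) * (x - s)
    lo_val = 0.0 if np.isneginf(l) else F(l)
    return F(hi) - lo_val


def conditional_mean_costs(model: CostModel, n_bins: int):
    """Per-bin conditional mean cost of each action given the bin of delta.

    Returns (edges, mean_c_ap, mean_c_av) with bins of equal mass 1/n_bins.
    """
    s = model.scale
    edges = cost_bin_edges(model, n_bins)
    mass = 1.0 / n_bins
    m_ap = np.empty(n_bins)
    m_av = np.empty(n_bins)
    for k in range(n_bins):
        l, u = edges[k], edges[k + 1]
        # E[max(0, -delta); bin] and, by symmetry, E[max(0, delta); bin]
        neg = _neg_part_mass_integral(l, u, s)
        pos = _neg_part_mass_integral(-u, -l, s)
        m_ap[k] = s / 2.0 + neg / mass
        m_av[k] = s / 2.0 + pos / mass
    return edges, m_ap, m_av


# ---------------------------------------------------------------------------
# MDP construction and solvers

def _belief_transition(action: str, m: int, env: EnvParams) -> sparse.csr_matrix:
    """Lattice-to-lattice transition matrix under one action (n_g x n_g)."""
    P = build_transition_matrix(env)
    E = emission_matrix(env, action)
    beliefs = lattice_beliefs(m)
    index_map = lattice_index_map(m)
    n_g = beliefs.shape[0]
    rows, cols, vals = [], [], []
    for g in range(n_g):
        b = beliefs[g]
        py = b @ E
        for y in range(3):
            if py[y] <= 0.0:
                continue
            child = ((b * E[:, y]) / py[y]) @ P
            verts, w = barycentric_round(child, m)
            for k in range(3):
                if w[k] <= 0.0:
                    continue
                key = (int(verts[k, 0]), int(verts[k, 1]))
                rows.append(g)
                cols.append(index_map[key])
                vals.append(py[y] * w[k])
    T = sparse.csr_matrix((vals, (rows, cols)), shape=(n_g, n_g))
    return T


def build_quantized_mdp(cfg: LPConfig, env: EnvParams, costs: CostModel):
    """Finite MDP over (lattice belief, cost bin): transitions and rewards.

    Returns (P_a dict of (n_s x n_s) sparse matrices, r dict of (n_s,) reward
    vectors, n_g, n_b).  State index = g * n_b + beta.
    """
    m = cfg.m
    n_b = cfg.n_cost_bins
    beliefs = lattice_beliefs(m)
    n_g = beliefs.shape[0]
    _, m_ap, m_av = conditional_mean_costs(costs, n_b)
    w = reinforcement_weights(env)
    R_ap = beliefs @ w
    bin_mix = np.full((n_b, n_b), 1.0 / n_b)
    P, r = {}, {}
    for a in ("ap", "av"):
        T = _belief_transition(a, m, env)
        P[a] = sparse.kron(T, sparse.csr_matrix(bin_mix), format="csr")
        if a == "ap":
            r[a] = (R_ap[:, None] - m_ap[None, :]).ravel()
        else:
            r[a] = np.tile(-m_av, n_g)
    return P, r, n_g, n_b


def relative_value_iteration(P, r, tol: float = 1e-9, max_iter: int = 200000,
                             h0: np.ndarray | None = None):
    """Average-reward relative value iteration on the finite MDP.

    Independent of the LP route; returns (gain, bias h, greedy action array).
    """
    n_s = r["ap"].shape[0]
    h = np.zeros(n_s) if h0 is None else np.asarray(h0, dtype=float).copy()
    ref = 0
    gain = 0.0
    for _ in range(max_iter):
        q_ap = r["ap"] + P["ap"] @ h
        q_av = r["av"] + P["av"] @ h
        new = np.maximum(q_ap, q_av)
        gain = new[ref]
        new = new - gain
        if np.max(np.abs(new - h)) < tol:
            h = new
            break
        h = new
    actions = np.where(q_ap >= q_av, 0, 1)  # 0 = ap, 1 = av
    return gain, h, actions


class LPPolicy(Policy):
    """Deterministic policy on the quantized (belief, cost-bin) space."""

    name = "lp_reward_rate"

    def __init__(self, cfg: LPConfig, env: EnvParams, costs: CostModel,
                 action_table: np.ndarray, rate: float):
        self.cfg = cfg
        self.env = env
        self.costs = costs
        self.action_table = action_table            # (n_g, n_b) of 0/1
        self.rate = rate
        self._m = cfg.m
        self._index_map = lattice_index_map(cfg.m)
        self._edges = cost_bin_edges(costs, cfg.n_cost_bins)

    def decide(self, b: BeliefState, c_ap: float, c_av: float) -> str:
        g = nearest_lattice_index(b.probs, self._m, self._index_map)
        delta = c_av - c_ap
        beta = int(np.clip(np.searchsorted(self._edges, delta) - 1,
                           0, self.cfg.n_cost_bins - 1))
        return "ap" if self.action_table[g, beta] == 0 else "av"

    def descriptor(self) -> dict:
        return {"name": self.name, "lattice_spacing": self.cfg.lattice_spacing,
                "n_cost_bins": self.cfg.n_cost_bins, "rate": self.rate}


def lp_reward_rate_policy(cfg: LPConfig, env: EnvParams,
                          costs: CostModel) -> LPPolicy:
    """Solve the occupation-measure LP; return the induced policy and rate.

    The achieved long-run average reward is available as ``policy.rate``.
    """
    P, r, n_g, n_b = build_quantized_mdp(cfg, env, costs)
    n_s = n_g * n_b
    # variables: x(s, ap) for all s, then x(s, av)
    c = -np.concatenate([r["ap"], r["av"]])
    I = sparse.identity(n_s, format="csr")
    balance = sparse.hstack([I - P["ap"].T, I - P["av"].T], format="csr")
    norm = sparse.csr_matrix(np.ones((1, 2 * n_s)))
    A_eq = sparse.vstack([balance, norm], format="csr")
    b_eq = np.zeros(n_s + 1)
    b_eq[-1] = 1.0
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"average-reward LP failed: {res.message}")
    rate = -res.fun
    # The duals of the balance constraints give a bias function h that is
    # valid on the support of the occupation measure only; complete it on the
    # transient states by Bellman iteration seeded from the duals, so the
    # policy is well-defined over the whole belief simplex.
    h0 = -np.asarray(res.eqlin.marginals[:n_s])
    gain, h, _ = relative_value_iteration(P, r, tol=1e-10, max_iter=100_000,
                                          h0=h0)
    if abs(gain - rate) > 1e-6 * max(1.0, abs(rate)):  # pragma: no cover
        raise RuntimeError(
            f"bias completion gain {gain} inconsistent with LP rate {rate}")
    q_ap = r["ap"] + P["ap"] @ h
    q_av = r["av"] + P["av"] @ h
    actions = np.where(q_ap >= q_av, 0, 1).reshape(n_g, n_b)
    # sanity: occupation measure must agree with the dual policy wherever the
    # state is actually visited
    x = res.x
    occ_ap, occ_av = x[:n_s], x[n_s:]
    visited = (occ_ap + occ_av) > 1e-9
    occ_actions = np.where(occ_ap >= occ_av, 0, 1)
    mismatch = np.mean(occ_actions[visited] != actions.ravel()[visited])
    if mismatch > 0.05:  # pragma: no cover - diagnostic guard
        raise RuntimeError(
            f"LP dual policy disagrees with occupation measure on "
            f"{mismatch:.1%} of visited states")
    return LPPolicy(cfg, env, costs, actions, rate)
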