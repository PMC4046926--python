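"""Stochastic costs of responding.

Both actions carry i.i.d. exponentially distributed costs (scale ``s``), drawn
fresh on every trial.  Decisions depend on the costs only through their
difference, whose law is Laplace(0, s); this is what injects trial-to-trial
variability into otherwise deterministic belief-based policies.  The provident
policy needs the expectation of a max against that Laplace offset in closed
form, provided here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CostModel", "sample_costs", "laplace_diff_cdf",
           "expected_max_with_laplace_offset"]


@dataclass(frozen=True)
class CostModel:
    """Scale of the exponential per-action costs (reward units)."""

    scale: float = 0.3

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("cost scale must be positive")

    @property
    def mean_cost(self) -> float:
        # exponential: mean == scale
        return self.scale

    def diff_distribution(self) -> stats.rv_continuous:
        """Law of the cost difference c_av - c_ap: Laplace(0, scale)."""
        return stats.laplace(loc=0.0, scale=self.scale)


def sample_costs(model: CostModel, rng: np.random.Generator,
                 size: int | None = None):
    """Independent (c_ap, c_av) draws; the effective reward of an action is
    its reinforcement minus its cost."""
    c_ap = rng.exponential(model.scale, size=size)
    c_av = rng.exponential(model.scale, size=size)
    if size is None:
        return float(c_ap), float(c_av)
    return c_ap, c_av


def laplace_diff_cdf(x, model: CostModel):
    """CDF of the Laplace(0, scale) cost difference at ``x``."""
    return stats.laplace.cdf(x, loc=0.0, scale=model.scale)


def expected_max_with_laplace_offset(A, B, model: CostModel):
    """E[max(A, B + D)] with D ~ Laplace(0, scale), in closed form.

    Splitting the Laplace density at the crossing point A - B gives

        E[max(A, B + D)] = max(A, B) + (scale / 2) * exp(-|A - B| / scale),

    validated against adaptive quadrature in the test suite.  Accepts arrays.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    s = model.scale
    out = np.maximum(A, B) + 0.5 * s * np.exp(-np.abs(A - B) / s)
    if out.ndim == 0:
        return float(out)
    return out
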