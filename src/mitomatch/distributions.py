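"""Weighted distributions on integer support.

The common return type for unconditional and conditioned match-count
distributions and for meiosis-distance distributions.
"""
from __future__ import annotations

import numpy as np

_QUANTILE_EPS = 1e-12


class WeightedDistribution:
    """Integer support values with nonnegative weights.

    Weights are normalized to sum to 1; duplicate support values are
    aggregated.  The quantile function is the weighted inverse empirical CDF
    (type 1): the smallest support value whose cumulative weight reaches q.
    """

    def __init__(self, support, weights=None, *, ess: float | None = None):
        support = np.asarray(support)
        if support.size == 0:
            raise ValueError("empty support")
        if weights is None:
            weights = np.ones(support.size)
        weights = np.asarray(weights, dtype=float)
        if weights.shape != support.shape:
            raise ValueError("support and weights must have the same shape")
        if (weights < 0).any():
            raise ValueError("weights must be nonnegative")
        total = weights.sum()
        if total <= 0:
            raise ValueError("total weight must be positive")
        order = np.argsort(support, kind="stable")
        support = support[order]
        weights = weights[order]
        # Aggregate duplicate support values.
        uniq, start = np.unique(support, return_index=True)
        agg = np.add.reduceat(weights, start)
        self.support = uniq
        self.weights = agg / total
        self._cum = np.cumsum(self.weights)
        #: Importance-sampling effective sample size, if applicable.
        self.ess = ess

    @classmethod
    def from_values(cls, values, weights=None, **kw) -> "WeightedDistribution":
        return cls(np.asarray(values), weights, **kw)

    def __len__(self) -> int:
        return int(self.support.size)

    def cdf(self, x) -> np.ndarray | float:
        idx = np.searchsorted(self.support, x, side="right")
        cum = np.concatenate([[0.0], self._cum])
        out = cum[idx]
        return float(out) if np.isscalar(x) else out

    def quantile(self, q):
        """Smallest support value with CDF >= q (right-continuous, monotone)."""
        q_arr = np.atleast_1d(np.asarray(q, dtype=float))
        if ((q_arr < 0) | (q_arr > 1)).any():
            raise ValueError("quantile levels must be in [0, 1]")
        idx = np.searchsorted(self._cum, q_arr - _QUANTILE_EPS, side="left")
        idx = np.minimum(idx, self.support.size - 1)
        out = self.support[idx]
        return out[0] if np.isscalar(q) else out

    def median(self):
        return self.quantile(0.5)

    def mean(self) -> float:
        return float(np.dot(self.support, self.weights))
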