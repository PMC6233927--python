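"""Conditioning match-count distributions on an observed database count.

A reference database of size n is modelled as a uniform random sample,
without replacement, from the live population other than the PoI.  Given a
PoI whose haplotype is carried by x other live individuals, the database
count m of that haplotype is hypergeometric.  Importance-sampling
reweighting turns unconditional PoI draws into the distribution of x
conditional on observing m: each sampled x is weighted by the
hypergeometric likelihood of the observation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distributions import WeightedDistribution

#: Effective sample sizes below this default are flagged as unreliable.
DEFAULT_MIN_ESS = 200.0


@dataclass(frozen=True)
class ConditionalSpec:
    """An observed database count: ``m`` copies in a database of size ``n``
    drawn from a live population of ``n_live``."""

    n: int
    m: int
    n_live: int

    def __post_init__(self):
        if not 0 <= self.m <= self.n <= self.n_live:
            raise ValueError("need 0 <= m <= n <= n_live")


def db_count_likelihood(x, spec: ConditionalSpec, *, include_poi: bool = False):
    """P(database count = m | population match count = x).

    Hypergeometric: m successes when drawing ``spec.n`` individuals without
    replacement from the ``n_live - 1`` live individuals other than the PoI,
    of whom x carry the PoI's haplotype.  ``include_poi`` makes the PoI
    itself eligible for the database (pool ``n_live``, ``x + 1`` carriers).
    Impossible observations get probability 0.
    """
    x = np.asarray(x)
    if (x < 0).any() or (x > spec.n_live - 1).any():
        raise ValueError("need 0 <= x <= n_live - 1")
    if include_poi:
        pool, good = spec.n_live, x + 1
    else:
        pool, good = spec.n_live - 1, x
    if spec.n > pool:
        raise ValueError(f"database size {spec.n} exceeds eligible pool {pool}")
    p = stats.hypergeom.pmf(spec.m, pool, good, spec.n)
    return float(p) if np.isscalar(p) or p.ndim == 0 else p


def conditional_distribution(
    samples,
    spec: ConditionalSpec,
    *,
    include_poi: bool = False,
    min_ess: float = DEFAULT_MIN_ESS,
) -> WeightedDistribution:
    """Importance-sampling estimate of the conditional match-count distribution.

    ``samples`` is a sequence of match counts (ints or
    :class:`~mitomatch.matching.MatchSample`).  Each sampled x is weighted by
    :func:`db_count_likelihood`; weights are normalized and the weighted
    distribution returned with its effective sample size
    ``ESS = (sum w)^2 / sum w^2`` attached (a warning is issued below
    ``min_ess``).
    """
    xs = np.asarray([getattr(s, "x", s) for s in samples], dtype=np.int64)
    if xs.size == 0:
        raise ValueError("no samples")
    ux, inv = np.unique(xs, return_inverse=True)
    w = np.asarray(db_count_likelihood(ux, spec, include_poi=include_poi))[inv]
    total = w.sum()
    if total <= 0:
        raise ValueError(
            "all importance weights are zero for this (n, m); the observation is "
            "incompatible with every simulated match count — simulate more PoIs "
            "or reconsider the conditioning spec"
        )
    ess = float(total**2 / np.square(w).sum())
    if ess < min_ess:
        warnings.warn(
            f"effective sample size {ess:.1f} < {min_ess:g}; "
            "conditional quantiles may be unreliable",
            stacklevel=2,
        )
    return WeightedDistribution(xs, w, ess=ess)
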