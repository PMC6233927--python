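"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's fast paths: distances by exhaustive
ancestor enumeration, mutation dropping by literal per-site Bernoulli
draws, conditioning by rejection sampling, database likelihoods by
exhaustive enumeration.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def brute_meioses(genealogy, a, b):
    """Meiosis distance by full ancestor enumeration (min total depth over
    all common matrilineal ancestors)."""

    def chain(x):
        depths = {x: 0}
        cur, d = x, 0
        while cur[0] > 0:
            cur = (cur[0] - 1, int(genealogy.mothers[cur[0]][cur[1]]))
            d += 1
            depths[cur] = d
        return depths

    ca, cb = chain(tuple(a)), chain(tuple(b))
    common = [ca[k] + cb[k] for k in ca if k in cb]
    return min(common) if common else math.inf


def founder_of_live(genealogy):
    """Founder (generation-0 index) of every live individual, by climbing."""
    gens, idxs = genealogy.live_index_arrays()
    out = np.empty(gens.size, dtype=np.int64)
    for k in range(gens.size):
        g, i = int(gens[k]), int(idxs[k])
        while g > 0:
            i = int(genealogy.mothers[g][i])
            g -= 1
        out[k] = i
    return out


def bernoulli_meiosis_flips(model, rates, n_meioses, rng):
    """Literal per-site Bernoulli mutation: a (n_meioses, genome_length)
    0/1 matrix of flips, site s flipping with its region's rate."""
    per_site = np.repeat(rates, model.n_sites)
    return (rng.random((n_meioses, model.genome_length)) < per_site).astype(np.int8)


def rejection_conditional(xs, spec, n_draws, rng):
    """Conditional match counts by rejection sampling.

    For each retained draw, pick one unconditional PoI sample x, simulate its
    database count (hypergeometric, pool = n_live - 1, x carriers), and keep
    x iff the count equals m.
    """
    from scipy import stats

    idx = rng.integers(0, len(xs), size=n_draws)
    x = np.asarray(xs)[idx]
    m_sim = stats.hypergeom.rvs(spec.n_live - 1, x, spec.n, random_state=rng)
    return x[m_sim == spec.m]


def enumerate_db_likelihood(n_live, x, n, m):
    """P(database count = m) by exhaustive enumeration of all databases of
    size n drawn from the n_live - 1 non-PoI individuals (x of them match)."""
    pool = n_live - 1
    hits = 0
    total = 0
    for combo in itertools.combinations(range(pool), n):
        total += 1
        if sum(1 for i in combo if i < x) == m:
            hits += 1
    return hits / total
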