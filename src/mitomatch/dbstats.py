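"""Haplotype-diversity summaries of random databases.

Random databases drawn from simulated live populations are summarised by
their numbers of distinct haplotypes, singletons (haplotypes seen once) and
doubletons (seen twice), for broad-brush comparison with empirical
databases.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import LivePopulation
from .utils import as_rng

#: Reference diversity of two empirical whole-mitogenome databases.
US_DATABASE = {"size": 263, "distinct": 259, "singletons": 255, "doubletons": 4}
IRANIAN_DATABASE = {"size": 352, "distinct": 315, "singletons": 286, "doubletons": 24}


@dataclass(eq=False)
class DatabaseSample:
    """One random database: its haplotype multiset and diversity counts."""

    size: int
    haplotypes: np.ndarray  # haplotype ID per database entry

    def __post_init__(self):
        if self.haplotypes.size != self.size:
            raise ValueError("haplotype multiset does not match size")
        _, counts = np.unique(self.haplotypes, return_counts=True)
        self.distinct = int(counts.size)
        self.singletons = int((counts == 1).sum())
        self.doubletons = int((counts == 2).sum())


def sample_database(live, n: int, seed=None) -> DatabaseSample:
    """Draw ``n`` individuals uniformly without replacement and tally haplotypes.

    ``live`` may be a :class:`~mitomatch.haplotypes.LivePopulation` or a
    plain array of haplotype IDs (e.g. an empirical database treated as a
    population).
    """
    hap = live.hap if isinstance(live, LivePopulation) else np.asarray(live)
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > hap.size:
        raise ValueError(f"database size {n} exceeds population size {hap.size}")
    rng = as_rng(seed)
    picked = rng.choice(hap.size, size=n, replace=False)
    return DatabaseSample(size=n, haplotypes=hap[picked])


def diversity_report(databases) -> pd.DataFrame:
    """Boxplot-style summary per database size.

    For each size group and each of the distinct/singleton/doubleton counts:
    quartiles and median, whiskers at the most extreme observations within
    1.5 x IQR of the quartiles, and the number of outliers beyond them.
    """
    databases = list(databases)
    if not databases:
        raise ValueError("no databases")
    df = pd.DataFrame(
        {
            "size": [d.size for d in databases],
            "distinct": [d.distinct for d in databases],
            "singletons": [d.singletons for d in databases],
            "doubletons": [d.doubletons for d in databases],
        }
    )
    rows = []
    for size, grp in df.groupby("size"):
        for stat in ("distinct", "singletons", "doubletons"):
            v = grp[stat].to_numpy(dtype=float)
            q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75])
            iqr = q75 - q25
            lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
            inside = v[(v >= lo_fence) & (v <= hi_fence)]
            rows.append(
                {
                    "size": int(size),
                    "statistic": stat,
                    "n": int(v.size),
                    "q25": q25,
                    "median": med,
                    "q75": q75,
                    "whisker_low": float(inside.min()),
                    "whisker_high": float(inside.max()),
                    "n_outliers": int(v.size - inside.size),
                }
            )
    return pd.DataFrame(rows)
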