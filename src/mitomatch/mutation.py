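"""Region-partitioned mitogenome mutation model.

The mitogenome is partitioned into four regions — hypervariable control
region (HVS1+HVS2), protein-coding codon positions 1+2 (PC1+PC2), codon
position 3 (PC3), and rRNA+tRNA — each with a per-site mutation-rate
95% interval (units: mutations per site per 10^7 generations, assuming
25-year generations).  Two published rate schemes are shipped: "rieux"
(16,070 sites) and "oversti" (16,494 sites; its control region is delimited
differently, hence the different total).

For simulation, one per-site rate per region is realized by drawing from a
normal distribution whose 95% interval matches the published bounds; the
same realized rate applies to every site of the region and every meiosis of
one sequence-evolution replicate.  Analytic summaries (mean genome rate,
expected mutation counts, multiple-hit probabilities) use the interval
midpoints.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats

from .demography import Genealogy
from .haplotypes import FounderPool, HaplotypeTable, LivePopulation
from .utils import as_rng

log = logging.getLogger(__name__)

#: Table rates are per site per 1e7 generations.
RATE_SCALE = 1e-7

#: Fixed region order of the partition.
REGION_ORDER = ("HVS1+HVS2", "PC1+PC2", "PC3", "rRNA+tRNA")

RIEUX = "rieux"
OVERSTI = "oversti"


@dataclass(frozen=True)
class RegionSpec:
    """One region of the mitogenome partition.

    ``rate_low``/``rate_high`` are the bounds of the 95% highest-posterior-
    density interval of the per-site rate, per 10^7 generations.
    """

    name: str
    n_sites: int
    rate_low: float
    rate_high: float

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0 < self.rate_low <= self.rate_high:
            raise ValueError("need 0 < rate_low <= rate_high")


@dataclass(frozen=True)
class MutationModel:
    """An ordered region partition with per-region rate intervals."""

    scheme_name: str
    regions: tuple

    def __post_init__(self):
        if len(self.regions) == 0:
            raise ValueError("model needs at least one region")

    @property
    def genome_length(self) -> int:
        return int(sum(r.n_sites for r in self.regions))

    @property
    def n_sites(self) -> np.ndarray:
        return np.asarray([r.n_sites for r in self.regions], dtype=np.int64)

    @property
    def offsets(self) -> np.ndarray:
        """0-based start position of each region within the genome."""
        return np.concatenate([[0], np.cumsum(self.n_sites)[:-1]])


def load_mutation_model(scheme: str) -> MutationModel:
    """Load a shipped rate scheme ("rieux" or "oversti") from packaged data."""
    scheme = scheme.lower()
    rows = []
    data = resources.files("mitomatch.data").joinpath("mutation_rates.tsv").read_text()
    for line in data.splitlines()[1:]:
        sch, region, n_sites, lo, hi = line.split("\t")
        if sch == scheme:
            rows.append(RegionSpec(region, int(n_sites), float(lo), float(hi)))
    if not rows:
        raise ValueError(f"unknown mutation scheme {scheme!r}; use 'rieux' or 'oversti'")
    rows.sort(key=lambda r: REGION_ORDER.index(r.name))
    return MutationModel(scheme, tuple(rows))


def region_midpoint_rates(model: MutationModel) -> np.ndarray:
    """Midpoint per-site rate per region, per generation."""
    return np.asarray(
        [(r.rate_low + r.rate_high) / 2.0 * RATE_SCALE for r in model.regions]
    )


def mean_genome_rate(model: MutationModel) -> float:
    """Expected mutations per mitogenome per generation at midpoint rates."""
    return float(np.dot(model.n_sites, region_midpoint_rates(model)))


def expected_mutations(model: MutationModel, n_generations: int) -> float:
    """Expected mutation count on one line of descent over ``n_generations``."""
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    return mean_genome_rate(model) * n_generations


def prob_any_double_hit(model: MutationModel, n_generations: int) -> float:
    """Probability that any site is hit by >= 2 mutations on one lineage.

    Per-site mutation counts over ``n_generations`` are modelled as
    Poisson(midpoint rate x generations); a doubly-hit site reverts to (or
    re-leaves) its original state, so this is the chance the observed
    sequence differs from the naive single-hit accumulation.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    lam = region_midpoint_rates(model) * n_generations
    log_p_le1 = stats.poisson.logcdf(1, lam)
    return float(-np.expm1(np.dot(model.n_sites, log_p_le1)))


@dataclass(eq=False)
class RateRealization:
    """One realized per-site rate per region (per generation).

    Applies to every site of the region and every meiosis of one
    sequence-evolution replicate.
    """

    scheme_name: str
    rates: np.ndarray
    n_truncated: int = 0

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if (self.rates < 0).any():
            raise ValueError("realized rates must be >= 0")


def draw_rate_realization(model: MutationModel, seed=None) -> RateRealization:
    """Draw per-region rates from Normal(midpoint, (U - L) / 3.92), per generation.

    The (L, U) bounds are read as a symmetric 95% normal interval.  Negative
    draws (vanishingly rare for the shipped intervals) are resampled and
    counted in ``n_truncated``.
    """
    rng = as_rng(seed)
    mid = region_midpoint_rates(model)
    sd = np.asarray(
        [(r.rate_high - r.rate_low) / (2 * 1.96) * RATE_SCALE for r in model.regions]
    )
    rates = rng.normal(mid, sd)
    n_trunc = 0
    neg = rates < 0
    while neg.any():
        n_trunc += int(neg.sum())
        rates[neg] = rng.normal(mid[neg], sd[neg])
        neg = rates < 0
    if n_trunc:
        log.warning("rate realization truncated at 0 (%d resamples)", n_trunc)
    return RateRealization(model.scheme_name, rates, n_trunc)


def drop_mutations(
    genealogy: Genealogy,
    model: MutationModel,
    realization: RateRealization,
    pool: FounderPool,
    founder_assignment: np.ndarray,
    seed=None,
) -> tuple[HaplotypeTable, LivePopulation]:
    """Evolve sequences down the genealogy: founder assignment + per-meiosis flips.

    At each mother-child transmission every site flips independently with its
    region's realized rate (a 0 becomes a 1 and vice versa).  For speed, the
    number of flips per meiosis and region is drawn as
    Binomial(n_sites, rate) and the flipped sites are then placed uniformly
    without replacement within the region — exactly equivalent to independent
    per-site Bernoulli flips.

    Returns the table of distinct realized haplotypes and the live
    population's haplotype assignment.
    """
    if pool.genome_length != model.genome_length:
        raise ValueError("founder pool genome length does not match the model")
    if len(realization.rates) != len(model.regions):
        raise ValueError("realization does not match the model's regions")
    assignment = np.asarray(founder_assignment, dtype=np.int64)
    n_founders = genealogy.n_females(0)
    if assignment.size != n_founders:
        raise ValueError(
            f"founder_assignment has {assignment.size} entries, expected {n_founders}"
        )
    rng = as_rng(seed)
    table = HaplotypeTable(model.genome_length)
    pool_ids = np.asarray([table.add_base(v) for v in pool.variants], dtype=np.int32)
    hap = pool_ids[assignment].astype(np.int32)

    n_sites = model.n_sites
    offsets = model.offsets
    rates = realization.rates
    n_regions = len(model.regions)
    live_start = genealogy.live_start

    live_blocks: list[np.ndarray] = []
    if live_start == 0:
        live_blocks.append(hap.copy())
    for g in range(1, genealogy.n_generations):
        mothers = genealogy.mothers[g]
        hap = hap[mothers]
        counts = [
            rng.binomial(int(n_sites[r]), rates[r], size=mothers.size)
            for r in range(n_regions)
        ]
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        for child in np.flatnonzero(total):
            flips: list[int] = []
            for r in range(n_regions):
                c = int(counts[r][child])
                if c == 1:
                    flips.append(int(offsets[r]) + int(rng.integers(n_sites[r])))
                elif c:
                    flips.extend(
                        (int(offsets[r]) + rng.choice(int(n_sites[r]), c, replace=False)).tolist()
                    )
            hap[child] = table.mutate(int(hap[child]), flips)
        if g >= live_start:
            live_blocks.append(hap.copy())

    live_gens = np.arange(live_start, genealogy.n_generations)
    live = LivePopulation(
        hap=np.concatenate(live_blocks).astype(np.int64),
        generations=live_gens,
        block_sizes=np.asarray([genealogy.n_individuals(g) for g in live_gens]),
        n_females=np.asarray([genealogy.n_females(g) for g in live_gens]),
    )
    return table, live
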