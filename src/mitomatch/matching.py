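"""Person-of-interest sampling, match counting, and the replicate protocol.

A person of interest (PoI) is drawn uniformly from the live population; the
match count x is the number of *other* live individuals whose mitogenome is
identical to the PoI's.  For a configurable fraction of PoIs the meiosis
distance to every matching individual is recorded.

:func:`run_protocol` orchestrates the full study design: per demographic
scenario, several independent genealogies; per genealogy and mutation
scheme, several sequence-evolution replicates (founder assignment, rate
realization, mutation dropping); per live population, a fixed number of PoI
draws.  Defaults follow the protocol of five genealogies x five sequence
replicates x 10,000 PoIs (250,000 PoIs per scenario-scheme combination),
with distances recorded for 10% of PoIs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import DemographyScenario, Genealogy, bulk_pair_meioses, simulate_genealogy
from .distributions import WeightedDistribution
from .haplotypes import LivePopulation, assign_founders, synth_founders, us_database_spectrum
from .mutation import MutationModel, draw_rate_realization, drop_mutations, load_mutation_model
from .utils import as_rng, stream

log = logging.getLogger(__name__)


@dataclass(eq=False)
class MatchSample:
    """One PoI draw: the live index, its match count and optional distances."""

    poi: int
    x: int
    meioses: np.ndarray | None = None
    genealogy_rep: int = 0
    mutation_rep: int = 0

    def __post_init__(self):
        if self.x < 0:
            raise ValueError("match count must be >= 0")
        # Distances are recorded to matching *others*: length x under the
        # exclusive counting convention, x - 1 under the inclusive one.
        if self.meioses is not None and len(self.meioses) not in (self.x, self.x - 1):
            raise ValueError("recorded distances must have length x (or x - 1)")


def sample_pois(
    live: LivePopulation,
    n_pois: int,
    seed=None,
    *,
    genealogy: Genealogy | None = None,
    meioses_fraction: float = 0.0,
    include_poi: bool = False,
) -> list[MatchSample]:
    """Draw PoIs uniformly with replacement and count their mitogenome matches.

    The first ``meioses_fraction`` of PoIs (in draw order, deterministic
    given the seed) also record the meiosis distance to each matching
    individual, which requires ``genealogy``.  ``include_poi`` switches to
    the inclusive counting convention (x counts the PoI itself too).
    """
    if n_pois < 1:
        raise ValueError("n_pois must be >= 1")
    if live.size == 0:
        raise ValueError("live population is empty")
    n_recorded = int(n_pois * meioses_fraction)
    if n_recorded > 0 and genealogy is None:
        raise ValueError("recording meioses requires the genealogy")
    rng = as_rng(seed)
    pois = rng.integers(0, live.size, size=n_pois)
    counts = np.bincount(live.hap)
    x = counts[live.hap[pois]] - (0 if include_poi else 1)

    order = sorted_hap = None
    if n_recorded:
        order = np.argsort(live.hap, kind="stable")
        sorted_hap = live.hap[order]
        gens, idxs = genealogy.live_index_arrays()

    samples: list[MatchSample] = []
    for k in range(n_pois):
        p = int(pois[k])
        dists = None
        if k < n_recorded:
            h = live.hap[p]
            lo, hi = np.searchsorted(sorted_hap, [h, h + 1])
            matches = order[lo:hi]
            matches = matches[matches != p]
            if matches.size:
                ga, ia = live.locate(p)
                dists = bulk_pair_meioses(
                    genealogy,
                    np.full(matches.size, ga),
                    np.full(matches.size, ia),
                    gens[matches],
                    idxs[matches],
                )
            else:
                dists = np.empty(0)
        samples.append(MatchSample(poi=p, x=int(x[k]), meioses=dists))
    return samples


def match_count_distribution(samples) -> WeightedDistribution:
    """Empirical (equal-weight) distribution of the match count x."""
    if len(samples) == 0:
        raise ValueError("no samples")
    return WeightedDistribution.from_values([s.x for s in samples])


def matching_pair_meioses(samples) -> WeightedDistribution:
    """Pooled distribution of meiosis distances over all (PoI, match) pairs.

    Pairs whose matrilines do not coalesce within the genealogy (possible
    only when unrelated founders were assigned identical haplotypes and no
    mutation occurred on either lineage) are excluded and logged.
    """
    pooled: list[np.ndarray] = []
    n_unrelated = 0
    for s in samples:
        if s.meioses is not None and len(s.meioses):
            d = np.asarray(s.meioses, dtype=float)
            finite = np.isfinite(d)
            n_unrelated += int((~finite).sum())
            pooled.append(d[finite])
    if not pooled or sum(p.size for p in pooled) == 0:
        raise ValueError("no recorded matching-pair distances")
    if n_unrelated:
        log.info("excluded %d non-coalescing matching pairs", n_unrelated)
    return WeightedDistribution.from_values(np.concatenate(pooled).astype(np.int64))


@dataclass(eq=False)
class ProtocolResult:
    """Tables produced by :func:`run_protocol`."""

    matches: pd.DataFrame    # scenario, scheme, genealogy_rep, mutation_rep, poi_index, poi, x
    meioses: pd.DataFrame    # ... poi_index, meioses (one row per matching pair)
    populations: pd.DataFrame  # scenario, genealogy_rep, n_live

    def samples(self, scenario: str, scheme: str) -> np.ndarray:
        sub = self.matches
        sub = sub[(sub.scenario == scenario) & (sub.scheme == scheme)]
        return sub.x.to_numpy()

    def match_distribution(self, scenario: str, scheme: str) -> WeightedDistribution:
        return WeightedDistribution.from_values(self.samples(scenario, scheme))

    def meioses_distribution(self, scenario: str, scheme: str) -> WeightedDistribution:
        sub = self.meioses
        sub = sub[(sub.scenario == scenario) & (sub.scheme == scheme)]
        vals = sub.meioses.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no recorded matching-pair distances")
        return WeightedDistribution.from_values(vals.astype(np.int64))

    def n_live(self, scenario: str) -> int:
        sub = self.populations[self.populations.scenario == scenario]
        return int(sub.n_live.iloc[0])

    def summary(self, quantiles=(0.5, 0.95, 0.99)) -> pd.DataFrame:
        """Quantile table of x (and of meiosis distances where recorded),
        mirroring the layout of the published match-count tables."""
        rows = []
        for (scenario, scheme), _ in self.matches.groupby(["scenario", "scheme"], sort=False):
            dist = self.match_distribution(scenario, scheme)
            row = {"scenario": scenario, "scheme": scheme, "statistic": "matches"}
            for q in quantiles:
                row[f"q{int(q * 100)}"] = int(dist.quantile(q))
            rows.append(row)
            try:
                mdist = self.meioses_distribution(scenario, scheme)
            except (ValueError, KeyError):
                continue
            row = {"scenario": scenario, "scheme": scheme, "statistic": "meioses"}
            for q in quantiles:
                row[f"q{int(q * 100)}"] = int(mdist.quantile(q))
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.matches.to_csv(out / "matches.tsv", sep="\t", index=False)
        self.meioses.to_csv(out / "meioses.tsv", sep="\t", index=False)
        self.populations.to_csv(out / "populations.tsv", sep="\t", index=False)
        self.summary().to_csv(out / "summary.tsv", sep="\t", index=False)


def run_protocol(
    scenarios,
    schemes,
    n_genealogies: int = 5,
    n_mutation_reps: int = 5,
    n_pois: int = 10_000,
    meioses_fraction: float = 0.10,
    seed: int = 0,
    *,
    founder_pool_size: int = 263,
    founder_spectrum=None,
    include_poi: bool = False,
) -> ProtocolResult:
    """Run the full simulation protocol and collect result tables.

    Parameters
    ----------
    scenarios
        Iterable of :class:`DemographyScenario`.
    schemes
        Iterable of scheme names ("rieux"/"oversti") or
        :class:`MutationModel` instances.
    seed
        Master seed; every stage derives an independent, reproducible
        substream, so a replicate can be recomputed in isolation and a
        failed replicate does not perturb the others (it is logged and the
        run continues).
    founder_pool_size, founder_spectrum
        Synthetic founder database emulating the US-database diversity by
        default (263 entries, 259 distinct).
    """
    models = [
        m if isinstance(m, MutationModel) else load_mutation_model(m) for m in schemes
    ]
    scenarios = list(scenarios)
    if founder_spectrum is None and founder_pool_size == 263:
        founder_spectrum = us_database_spectrum()
    # One founder database per scheme (genome lengths differ between schemes).
    pools = {
        m.scheme_name: synth_founders(
            founder_pool_size,
            founder_spectrum,
            genome_length=m.genome_length,
            seed=stream(seed, "pool", k),
        )
        for k, m in enumerate(models)
    }

    match_rows = []
    meioses_rows = []
    pop_rows = []
    for si, scenario in enumerate(scenarios):
        for gj in range(n_genealogies):
            genealogy = simulate_genealogy(scenario, stream(seed, "genealogy", si, gj))
            pop_rows.append(
                {"scenario": scenario.label, "genealogy_rep": gj, "n_live": scenario.live_size}
            )
            for mk, model in enumerate(models):
                pool = pools[model.scheme_name]
                for rl in range(n_mutation_reps):
                    try:
                        realization = draw_rate_realization(
                            model, stream(seed, "rates", si, gj, mk, rl)
                        )
                        assignment = assign_founders(
                            pool,
                            genealogy.n_females(0),
                            stream(seed, "founders", si, gj, mk, rl),
                        )
                        _, live = drop_mutations(
                            genealogy,
                            model,
                            realization,
                            pool,
                            assignment,
                            stream(seed, "mutations", si, gj, mk, rl),
                        )
                        samples = sample_pois(
                            live,
                            n_pois,
                            stream(seed, "pois", si, gj, mk, rl),
                            genealogy=genealogy,
                            meioses_fraction=meioses_fraction,
                            include_poi=include_poi,
                        )
                    except Exception:
                        log.exception(
                            "replicate failed (scenario=%s scheme=%s genealogy=%d rep=%d); continuing",
                            scenario.label, model.scheme_name, gj, rl,
                        )
                        continue
                    for pi, s in enumerate(samples):
                        match_rows.append(
                            (scenario.label, model.scheme_name, gj, rl, pi, s.poi, s.x)
                        )
                        if s.meioses is not None:
                            for d in s.meioses:
                                meioses_rows.append(
                                    (scenario.label, model.scheme_name, gj, rl, pi, float(d))
                                )
            del genealogy

    matches = pd.DataFrame(
        match_rows,
        columns=["scenario", "scheme", "genealogy_rep", "mutation_rep", "poi_index", "poi", "x"],
    )
    meioses = pd.DataFrame(
        meioses_rows,
        columns=["scenario", "scheme", "genealogy_rep", "mutation_rep", "poi_index", "meioses"],
    )
    populations = pd.DataFrame(pop_rows, columns=["scenario", "genealogy_rep", "n_live"])
    return ProtocolResult(matches, meioses, populations)
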