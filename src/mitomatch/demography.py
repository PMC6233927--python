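"""Matrilineal Wright-Fisher demography: size trajectories and genealogies.

A population is a sequence of discrete, non-overlapping generations of
females (the mitochondrial lineage carriers).  Each female in generation
``g`` picks her mother uniformly at random among generation ``g - 1``'s
females, the standard Wright-Fisher construction: every female has the same
offspring-number distribution (Binomial(N, 1/N), approximately Poisson(1)).

The final ``n_live_generations`` generations (default 3) form the *live*
population: the individuals eligible as persons of interest, matches and
database members.  In live generations an equal number of males is simulated
as additional terminal children — males carry and can match a mitogenome but
never transmit one.

Individuals are addressed by ``(generation, index)`` pairs.  Within a
generation, indices ``[0, n_females)`` are females; in live generations the
males occupy ``[n_females, 2 * n_females)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .utils import as_rng

#: Sentinel distance for matrilines that do not coalesce within the
#: simulated genealogy (coalescence cannot precede the founder generation).
UNRELATED = float("inf")


@dataclass(eq=False)
class DemographyScenario:
    """Per-generation female population sizes plus the live-generation policy.

    Parameters
    ----------
    female_sizes
        Number of females per generation; index 0 is the founder generation,
        the last index is the present.
    n_live_generations
        How many final generations count as "live" (alive today).
    include_males
        Whether live generations also contain males (one per female).
    label
        Free-text scenario name, e.g. ``"300K_const"``.
    """

    female_sizes: np.ndarray
    n_live_generations: int = 3
    include_males: bool = True
    label: str = ""

    def __post_init__(self):
        sizes = np.asarray(self.female_sizes, dtype=np.int64)
        if sizes.ndim != 1 or sizes.size == 0:
            raise ValueError("female_sizes must be a non-empty 1-D sequence")
        if (sizes < 1).any():
            raise ValueError("all per-generation female sizes must be >= 1")
        if not 1 <= self.n_live_generations <= sizes.size:
            raise ValueError(
                f"n_live_generations must be in [1, {sizes.size}], "
                f"got {self.n_live_generations}"
            )
        self.female_sizes = sizes

    @property
    def n_generations(self) -> int:
        return int(self.female_sizes.size)

    @property
    def live_start(self) -> int:
        """Index of the first live generation."""
        return self.n_generations - self.n_live_generations

    def n_individuals(self, g: int) -> int:
        """Total individuals in generation ``g`` (females plus any males)."""
        n = int(self.female_sizes[g])
        # Males are children too, so they need a preceding generation (g >= 1).
        if self.include_males and g >= max(self.live_start, 1):
            n *= 2
        return n

    @property
    def live_size(self) -> int:
        """Total number of live individuals (both sexes)."""
        return sum(
            self.n_individuals(g)
            for g in range(self.live_start, self.n_generations)
        )


def build_constant_sizes(
    n_females: int, n_generations: int, *, label: str = "", **kwargs
) -> DemographyScenario:
    """Constant-size scenario: ``n_generations`` generations of ``n_females``."""
    if n_females < 1:
        raise ValueError("n_females must be a positive integer")
    if n_generations < 3:
        raise ValueError("n_generations must be >= 3")
    return DemographyScenario(
        np.full(n_generations, n_females, dtype=np.int64),
        label=label or f"const_{n_females}x{n_generations}",
        **kwargs,
    )


def build_growth_sizes(
    n_initial: int,
    growth_rate: float,
    n_constant: int,
    n_growth: int,
    *,
    exact_final: int | None = None,
    label: str = "",
    **kwargs,
) -> DemographyScenario:
    """Constant phase followed by geometric growth.

    The first ``n_constant`` generations have ``n_initial`` females; growth
    generation ``k`` (k = 1..n_growth) has ``round(n_initial * (1 + growth_rate)**k)``.
    ``exact_final``, if given, overrides the last generation's size (useful to
    hit a round target figure instead of the rounded compound value).
    """
    if n_initial < 1:
        raise ValueError("n_initial must be a positive integer")
    if growth_rate <= -1:
        raise ValueError("growth_rate must be > -1")
    if n_constant < 0 or n_growth < 0:
        raise ValueError("phase lengths must be >= 0")
    sizes = [n_initial] * n_constant
    sizes += [
        int(round(n_initial * (1.0 + growth_rate) ** k))
        for k in range(1, n_growth + 1)
    ]
    if not sizes:
        raise ValueError("trajectory is empty (n_constant + n_growth == 0)")
    if exact_final is not None:
        sizes[-1] = int(exact_final)
    return DemographyScenario(
        np.asarray(sizes, dtype=np.int64),
        label=label or f"growth_{n_initial}+{n_growth}@{growth_rate:g}",
        **kwargs,
    )


def scenario_300k_const() -> DemographyScenario:
    """50K females per generation for 1,200 generations; 300K live."""
    return build_constant_sizes(50_000, 1_200, label="300K_const")


def scenario_1p2m_const() -> DemographyScenario:
    """200K females per generation for 1,200 generations; 1.2M live."""
    return build_constant_sizes(200_000, 1_200, label="1.2M_const")


def scenario_1p2m_growth() -> DemographyScenario:
    """10,257 females for 1,000 generations, then 2%/generation growth for 150."""
    return build_growth_sizes(10_257, 0.02, 1_000, 150, label="1.2M_growth")


CANONICAL_SCENARIOS = {
    "300K_const": scenario_300k_const,
    "1.2M_const": scenario_1p2m_const,
    "1.2M_growth": scenario_1p2m_growth,
}


class Genealogy:
    """Mother-pointer genealogy of a simulated matrilineal population.

    ``mothers[g][i]`` is the index, within generation ``g - 1``'s females, of
    the mother of individual ``(g, i)``.  ``mothers[0]`` is ``None`` —
    founders have no recorded mother.
    """

    __slots__ = ("scenario", "mothers")

    def __init__(self, scenario: DemographyScenario, mothers: list):
        self.scenario = scenario
        self.mothers = mothers

    @property
    def n_generations(self) -> int:
        return self.scenario.n_generations

    @property
    def live_start(self) -> int:
        return self.scenario.live_start

    def n_individuals(self, g: int) -> int:
        return self.scenario.n_individuals(g)

    def n_females(self, g: int) -> int:
        return int(self.scenario.female_sizes[g])

    def is_female(self, g: int, i: int) -> bool:
        return i < self.n_females(g)

    def _check(self, g: int, i: int) -> None:
        if not 0 <= g < self.n_generations:
            raise IndexError(f"generation {g} out of range")
        if not 0 <= i < self.n_individuals(g):
            raise IndexError(f"individual {i} out of range for generation {g}")

    def live_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(generation, within-generation index) arrays for all live individuals,
        ordered by generation then index."""
        gens, idxs = [], []
        for g in range(self.live_start, self.n_generations):
            n = self.n_individuals(g)
            gens.append(np.full(n, g, dtype=np.int64))
            idxs.append(np.arange(n, dtype=np.int64))
        return np.concatenate(gens), np.concatenate(idxs)

    @property
    def live_size(self) -> int:
        return self.scenario.live_size


def simulate_genealogy(scenario: DemographyScenario, seed=None) -> Genealogy:
    """Simulate a Wright-Fisher matrilineal genealogy forward in time.

    Every non-founder (female, or male in a live generation) draws its mother
    independently and uniformly at random among the previous generation's
    females.  Reproducible for a fixed seed.
    """
    rng = as_rng(seed)
    sizes = scenario.female_sizes
    mothers: list = [None]
    for g in range(1, scenario.n_generations):
        n = scenario.n_individuals(g)
        mothers.append(rng.integers(0, sizes[g - 1], size=n, dtype=np.int32))
    return Genealogy(scenario, mothers)


def ancestors_to_root(genealogy: Genealogy, g: int, i: int) -> np.ndarray:
    """Matrilineal ancestor of ``(g, i)`` at every generation ``0..g``.

    Returns an array ``anc`` with ``anc[k]`` the index of the ancestor in
    generation ``k`` (``anc[g] == i``).
    """
    genealogy._check(g, i)
    anc = np.empty(g + 1, dtype=np.int64)
    anc[g] = i
    cur = i
    for gg in range(g, 0, -1):
        cur = int(genealogy.mothers[gg][cur])
        anc[gg - 1] = cur
    return anc


def meioses_between(genealogy: Genealogy, a, b):
    """Meiosis distance between individuals ``a`` and ``b`` (``(gen, idx)`` pairs).

    Counts mother-child transmissions along the matrilineal path through the
    most recent common matrilineal ancestor (MRCA):
    ``depth(a -> MRCA) + depth(b -> MRCA)``.  Returns :data:`UNRELATED`
    (``inf``) if the matrilines do not coalesce within the genealogy.
    """
    ga, ia = a
    gb, ib = b
    genealogy._check(ga, ia)
    genealogy._check(gb, ib)
    d = 0
    while ga > gb:
        ia = int(genealogy.mothers[ga][ia])
        ga -= 1
        d += 1
    while gb > ga:
        ib = int(genealogy.mothers[gb][ib])
        gb -= 1
        d += 1
    while ia != ib:
        if ga == 0:
            return UNRELATED
        ia = int(genealogy.mothers[ga][ia])
        ib = int(genealogy.mothers[gb][ib])
        ga -= 1
        gb -= 1
        d += 2
    return d


def bulk_pair_meioses(
    genealogy: Genealogy,
    a_gen: np.ndarray,
    a_idx: np.ndarray,
    b_gen: np.ndarray,
    b_idx: np.ndarray,
) -> np.ndarray:
    """Vectorized :func:`meioses_between` over arrays of pairs.

    Returns a float array with ``inf`` for non-coalescing pairs.
    """
    ga = np.asarray(a_gen, dtype=np.int64).copy()
    ia = np.asarray(a_idx, dtype=np.int64).copy()
    gb = np.asarray(b_gen, dtype=np.int64).copy()
    ib = np.asarray(b_idx, dtype=np.int64).copy()
    ga0, gb0 = ga.copy(), gb.copy()
    n = ga.size
    out = np.full(n, np.inf)
    active = np.ones(n, dtype=bool)
    g = int(max(ga.max(initial=0), gb.max(initial=0)))
    while True:
        # Record pairs whose lineages have met at this level.
        both = active & (ga == g) & (gb == g)
        if both.any():
            hit = both & (ia == ib)
            if hit.any():
                out[hit] = (ga0[hit] - g) + (gb0[hit] - g)
                active &= ~hit
        if not active.any() or g == 0:
            break
        # Step every active lineage currently at this level up one generation.
        mom = genealogy.mothers[g]
        ma = active & (ga == g)
        if ma.any():
            ia[ma] = mom[ia[ma]]
            ga[ma] -= 1
        mb = active & (gb == g)
        if mb.any():
            ib[mb] = mom[ib[mb]]
            gb[mb] -= 1
        g -= 1
    return out


def random_pair_meioses(
    genealogy: Genealogy, n_pairs: int, seed=None
) -> np.ndarray:
    """Meiosis distances for random distinct pairs of live individuals.

    Pairs are drawn uniformly (with replacement across pairs, the two members
    always distinct).  Non-coalescing pairs appear as ``inf`` entries so that
    the caller can count "unrelated" outcomes separately.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    n_live = genealogy.live_size
    if n_live < 2:
        raise ValueError("need at least two live individuals")
    rng = as_rng(seed)
    gens, idxs = genealogy.live_index_arrays()
    a = rng.integers(0, n_live, size=n_pairs)
    b = rng.integers(0, n_live, size=n_pairs)
    clash = a == b
    while clash.any():
        b[clash] = rng.integers(0, n_live, size=int(clash.sum()))
        clash = a == b
    return bulk_pair_meioses(genealogy, gens[a], idxs[a], gens[b], idxs[b])


def coalescent_mean_pair_meioses(n_females: int) -> float:
    """Coalescent-theory mean meiosis distance of a random pair, constant size.

    Two matrilines in a Wright-Fisher population of ``N`` females coalesce at
    rate ``1/N`` per generation, so the expected time to the MRCA is ``N``
    generations and the expected meiosis distance is ``2 N``.
    """
    if n_females < 1:
        raise ValueError("n_females must be positive")
    return 2.0 * n_females
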