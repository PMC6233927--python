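"""Binary mitogenome haplotypes coded relative to the rCRS reference.

A haplotype is a binary vector over the mutation model's sites: 0 where the
sequence agrees with the reference, 1 where it differs.  Haplotypes are
stored sparsely as sorted arrays of variant positions; each distinct realized
sequence gets one integer ID, and every individual carries just that ID.

Identity is computed on the full genome vector, so lineages that converge
(e.g. by a back-mutation) are merged into the same haplotype ID.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .utils import as_rng


class HaplotypeTable:
    """Registry of distinct haplotypes with sparse storage and provenance.

    Each distinct haplotype records the sorted variant positions defining it
    (the identity key) plus, for mutation-derived haplotypes, the parent ID
    and flipped sites of the meiosis that first produced it, so sequences can
    also be reconstructed by walking the delta chain from a founder.
    """

    __slots__ = ("genome_length", "_index", "_keys", "_parent", "_flips")

    def __init__(self, genome_length: int):
        if not 1 <= genome_length <= 65535:
            raise ValueError("genome_length must be in [1, 65535]")
        self.genome_length = int(genome_length)
        self._index: dict[bytes, int] = {}
        self._keys: list[bytes] = []
        self._parent: list[int] = []
        self._flips: list[tuple] = []

    @property
    def n_distinct(self) -> int:
        return len(self._keys)

    def _register(self, key: bytes, parent: int, flips: tuple) -> int:
        hap_id = self._index.get(key)
        if hap_id is None:
            hap_id = len(self._keys)
            self._index[key] = hap_id
            self._keys.append(key)
            self._parent.append(parent)
            self._flips.append(flips)
        return hap_id

    def add_base(self, positions) -> int:
        """Register a founder haplotype given 0-based variant positions."""
        pos = np.asarray(positions, dtype=np.int64)
        if pos.size:
            if pos.min() < 0 or pos.max() >= self.genome_length:
                raise ValueError("variant position out of range")
            pos = np.sort(pos)
            if (np.diff(pos) == 0).any():
                raise ValueError("duplicate variant positions")
        return self._register(pos.astype(np.uint16).tobytes(), -1, ())

    def mutate(self, parent_id: int, flips) -> int:
        """Haplotype obtained from ``parent_id`` by flipping the given sites.

        Flipping is an involution: a site present in the parent's variant set
        is removed (back-mutation to reference), an absent one is added.
        """
        if len(flips) == 0:
            return parent_id
        parent = np.frombuffer(self._keys[parent_id], dtype=np.uint16)
        if len(flips) == 1:
            # Common case: a single flipped site; merge by hand.
            s = np.uint16(flips[0])
            k = int(np.searchsorted(parent, s))
            if k < parent.size and parent[k] == s:
                new = np.delete(parent, k)
            else:
                new = np.insert(parent, k, s)
        else:
            new = np.setxor1d(parent, np.asarray(flips, dtype=np.uint16))
        return self._register(new.tobytes(), parent_id, tuple(int(f) for f in flips))

    def variants(self, hap_id: int) -> np.ndarray:
        """Sorted 0-based variant positions of a haplotype."""
        return np.frombuffer(self._keys[hap_id], dtype=np.uint16).astype(np.int64)

    def vector(self, hap_id: int) -> np.ndarray:
        """Full binary genome vector (uint8) of a haplotype."""
        v = np.zeros(self.genome_length, dtype=np.uint8)
        v[self.variants(hap_id)] = 1
        return v

    def variants_by_deltas(self, hap_id: int) -> frozenset:
        """Variant set reconstructed by XOR-walking the delta chain to a founder.

        Used as an internal consistency check against :meth:`variants`.
        """
        chain = []
        cur = hap_id
        while self._parent[cur] >= 0:
            chain.append(self._flips[cur])
            cur = self._parent[cur]
        s = set(int(p) for p in self.variants(cur))
        for flips in reversed(chain):
            s.symmetric_difference_update(flips)
        return frozenset(s)


@dataclass(eq=False)
class FounderPool:
    """A pool of founder haplotypes emulating (or loaded from) a database.

    ``variants`` holds one sorted 0-based position array per pool entry;
    entries may repeat (a haplotype observed more than once in the database).
    """

    variants: list
    genome_length: int
    source: str = "synthetic"

    def __post_init__(self):
        for v in self.variants:
            if v.size and (v.min() < 0 or v.max() >= self.genome_length):
                raise ValueError("founder variant position out of range")

    @property
    def size(self) -> int:
        return len(self.variants)

    def _keys(self) -> list[bytes]:
        return [v.astype(np.uint16).tobytes() for v in self.variants]

    @property
    def n_distinct(self) -> int:
        return len(set(self._keys()))

    @property
    def multiplicities(self) -> np.ndarray:
        """Observed count of each distinct haplotype (descending order)."""
        from collections import Counter

        return np.asarray(
            sorted(Counter(self._keys()).values(), reverse=True), dtype=np.int64
        )


def _genome_length(model_or_length) -> int:
    return int(getattr(model_or_length, "genome_length", model_or_length))


def us_database_spectrum() -> tuple:
    """Haplotype frequency spectrum of the 263-genome US Caucasian database:
    259 distinct haplotypes — 255 singletons and 4 doubletons."""
    return (2, 2, 2, 2) + (1,) * 255


def synth_founders(
    n: int,
    spectrum=None,
    genome_length=16070,
    seed=None,
    sites_per_haplotype: tuple = (10, 40),
) -> FounderPool:
    """Generate a synthetic founder pool with a given frequency spectrum.

    Parameters
    ----------
    n
        Pool size (number of database entries).
    spectrum
        Multiplicities of the distinct haplotypes, summing to ``n``.
        Defaults to all singletons.
    genome_length
        Number of sites, or a mutation model (its ``genome_length`` is used).
    sites_per_haplotype
        Inclusive range for the number of variant sites per haplotype.
        Typical full-mitogenome haplotypes carry a few tens of differences
        from the rCRS.
    """
    genome_length = _genome_length(genome_length)
    if spectrum is None:
        spectrum = (1,) * n
    spectrum = tuple(int(m) for m in spectrum)
    if any(m < 1 for m in spectrum) or sum(spectrum) != n:
        raise ValueError(f"spectrum must be positive and sum to n={n}")
    lo, hi = sites_per_haplotype
    if not 1 <= lo <= hi:
        raise ValueError("sites_per_haplotype must satisfy 1 <= lo <= hi")
    # tiny genomes: cap at the number of available sites
    lo, hi = min(lo, genome_length), min(hi, genome_length)
    rng = as_rng(seed)
    seen: set[bytes] = set()
    distinct: list[np.ndarray] = []
    while len(distinct) < len(spectrum):
        k = int(rng.integers(lo, hi + 1))
        pos = np.sort(rng.choice(genome_length, size=k, replace=False)).astype(np.int64)
        key = pos.astype(np.uint16).tobytes()
        if key in seen:  # vanishingly rare; redraw to keep haplotypes distinct
            continue
        seen.add(key)
        distinct.append(pos)
    variants = []
    for hap, mult in zip(distinct, spectrum):
        variants.extend([hap] * mult)
    return FounderPool(variants, genome_length, source="synthetic")


def load_founders(path, genome_length) -> FounderPool:
    """Read a founder-haplotype file.

    One haplotype per line: an identifier, then optionally whitespace and a
    comma-separated list of 1-based variant positions (no positions = the
    reference itself).  Blank lines and ``#`` comments are skipped.
    ``genome_length`` may be an int or a mutation model.
    """
    genome_length = _genome_length(genome_length)
    variants: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(None, 1)
            if len(fields) == 1 or not fields[1].strip():
                variants.append(np.empty(0, dtype=np.int64))
                continue
            try:
                pos1 = [int(tok) for tok in fields[1].replace(" ", "").split(",") if tok]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed position list") from exc
            pos = np.asarray(pos1, dtype=np.int64) - 1  # 1-based in files
            if pos.size and (pos.min() < 0 or pos.max() >= genome_length):
                raise ValueError(
                    f"{path}:{lineno}: position out of range [1, {genome_length}]"
                )
            pos = np.sort(pos)
            if pos.size and (np.diff(pos) == 0).any():
                raise ValueError(f"{path}:{lineno}: duplicate variant position")
            variants.append(pos)
    return FounderPool(variants, genome_length, source="file")


def write_founders(path, pool: FounderPool, ids=None) -> None:
    """Write a founder pool in the :func:`load_founders` text format."""
    if ids is None:
        ids = [f"H{i + 1:04d}" for i in range(pool.size)]
    with open(path, "w") as fh:
        for name, v in zip(ids, pool.variants):
            if v.size:
                fh.write(f"{name}\t{','.join(str(int(p) + 1) for p in v)}\n")
            else:
                fh.write(f"{name}\n")


def assign_founders(pool: FounderPool, n_founders: int, seed=None) -> np.ndarray:
    """Assign each founder a pool entry uniformly at random with replacement.

    Sampling entries (not distinct haplotypes) weights each distinct haplotype
    by its observed multiplicity in the database.
    """
    if pool.size == 0:
        raise ValueError("founder pool is empty")
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    rng = as_rng(seed)
    return rng.integers(0, pool.size, size=n_founders, dtype=np.int64)


@dataclass(eq=False)
class LivePopulation:
    """Haplotype assignment of the live population.

    Live individuals are ordered by generation (oldest live generation first)
    and, within a generation, females before males.
    """

    hap: np.ndarray           # haplotype ID per live individual
    generations: np.ndarray   # generation label per block
    block_sizes: np.ndarray   # individuals per block
    n_females: np.ndarray     # females per block

    def __post_init__(self):
        self.offsets = np.concatenate(
            [[0], np.cumsum(np.asarray(self.block_sizes, dtype=np.int64))]
        )
        if self.hap.size != self.offsets[-1]:
            raise ValueError("haplotype array does not match block sizes")

    @property
    def size(self) -> int:
        return int(self.hap.size)

    def locate(self, i: int) -> tuple[int, int]:
        """Map a live index to a ``(generation, within-generation index)`` pair."""
        if not 0 <= i < self.size:
            raise IndexError(f"live index {i} out of range")
        b = int(np.searchsorted(self.offsets, i, side="right")) - 1
        return int(self.generations[b]), int(i - self.offsets[b])

    def sex(self, i: int) -> str:
        b = int(np.searchsorted(self.offsets, i, side="right")) - 1
        return "F" if (i - self.offsets[b]) < self.n_females[b] else "M"


def match_key(live: LivePopulation, i: int) -> int:
    """Haplotype identity token of live individual ``i``.

    Tokens are equal for two individuals iff their full binary genome vectors
    are identical (haplotype IDs are deduplicated on the full vector,
    including across founders and back-mutations).
    """
    return int(live.hap[i])
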