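"""Small shared helpers (random-number plumbing)."""
from __future__ import annotations

import numpy as np

RngLike = "int | np.random.SeedSequence | np.random.Generator | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator to a Generator.

    ``None`` gives fresh OS entropy; a Generator is passed through so callers
    can share a stream.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def stream(master_seed: int, *key) -> np.random.Generator:
    """Derive an independent, reproducible substream from an integer master seed.

    The key is a tuple of small ints/strings identifying the pipeline stage and
    replicate; strings are hashed to stable small ints so the stream depends
    only on (master_seed, key).
    """
    spawn_key = tuple(
        k if isinstance(k, (int, np.integer)) else _stable_hash(k) for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=spawn_key))


def _stable_hash(s: str) -> int:
    # Python's hash() is salted per process; use a fixed FNV-1a instead.
    h = 2166136261
    for b in s.encode():
        h = ((h ^ b) * 16777619) & 0xFFFFFFFF
    return h
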