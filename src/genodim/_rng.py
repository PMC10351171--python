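"""Deterministic seeding helpers.

Every stage of the pipeline draws from its own child generator derived from
a single master seed plus a path of string/int keys.  The derivation is
counter-based (stable hashes of the keys feed a ``SeedSequence``), so any
stage or replicate can be re-run in isolation and reproduce its stream.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["as_rng", "spawn_rng"]


def _key_to_int(key) -> int:
    digest = hashlib.blake2s(str(key).encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big")


def spawn_rng(seed: int, *path) -> np.random.Generator:
    """Child generator for ``path`` under ``seed``.

    ``spawn_rng(s, "simulate", rep, "historical")`` is a pure function of its
    arguments; distinct paths give statistically independent streams.
    """
    entropy = [int(seed)] + [_key_to_int(k) for k in path]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_rng(rng_or_seed) -> np.random.Generator:
    """Coerce an int seed, ``None`` or a Generator into a Generator."""
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)
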