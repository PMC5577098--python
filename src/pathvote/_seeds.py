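"""Deterministic seed derivation.

A single master seed fans out to every stage of the pipeline through
:class:`numpy.random.SeedSequence` spawn keys, so any stage (DE screening,
CV resampling, final refit, test-set resampling) can be re-run in isolation
and still reproduce the full run bit for bit.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["seed_sequence", "rng", "derive_int"]


def _key_part(part: int | str) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part)
    # stable 32-bit digest for string path elements
    return int.from_bytes(hashlib.blake2s(part.encode("utf-8"), digest_size=4).digest(), "big")


def seed_sequence(master_seed: int, *path: int | str) -> np.random.SeedSequence:
    """SeedSequence for a named sub-stream of the master seed."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(_key_part(p) for p in path))


def rng(master_seed: int, *path: int | str) -> np.random.Generator:
    """Generator seeded from a named sub-stream of the master seed."""
    return np.random.default_rng(seed_sequence(master_seed, *path))


def derive_int(master_seed: int, *path: int | str) -> int:
    """A 31-bit integer seed for APIs that take plain ints (e.g. scikit-learn)."""
    return int(seed_sequence(master_seed, *path).generate_state(1)[0] % (2**31))
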