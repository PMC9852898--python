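"""Deterministic random-stream derivation.

Every stochastic stage of the pipeline draws from a `numpy` Generator whose
SeedSequence is derived from the master seed plus a tuple of stage names, so
that adding or reordering stages never silently shifts another stage's stream.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["rng_for", "derive_seed"]


def _name_key(name: object) -> int:
    digest = hashlib.sha256(repr(name).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def rng_for(master_seed: int, *names: object) -> np.random.Generator:
    """Generator for the stage identified by ``names`` under ``master_seed``."""
    key = [int(master_seed) & 0x7FFFFFFF] + [_name_key(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(key))


def derive_seed(master_seed: int, *names: object) -> int:
    """A plain integer seed (< 2**31) for APIs that take one."""
    return int(rng_for(master_seed, *names).integers(0, 2**31 - 1))
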