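"""Deterministic random-stream derivation.

One master seed drives a whole simulation campaign.  Every sub-task (database
generation, Monte Carlo run r of grid cell c, ...) gets its own independent
`numpy` Generator derived through ``SeedSequence(master, spawn_key=...)``, a
counter-based scheme: streams are reproducible bit-for-bit, independent of
execution order, and safe to parallelise.
"""
from __future__ import annotations

import numpy as np

__all__ = ["as_rng", "derive_rng", "derive_seed"]


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, SeedSequence, Generator or None) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def derive_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Generator for the sub-stream identified by ``key`` under ``master_seed``."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def derive_seed(master_seed: int, *key: int) -> int:
    """A plain integer seed (< 2**31) for the sub-stream ``key``."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
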