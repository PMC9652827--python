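"""Shared helpers: seeded RNG fan-out and small numeric utilities."""

from __future__ import annotations

import hashlib

import numpy as np

MAX_SEED = 2**31 - 1


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from a global seed.

    Uses SHA-256 of ``"{seed}:{stage}"`` so every stage gets an independent
    stream regardless of execution order, and reruns are reproducible.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % MAX_SEED


def rng_from(seed: int | None, stage: str | None = None) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    if stage is not None:
        seed = stage_seed(seed, stage)
    return np.random.default_rng(seed)
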