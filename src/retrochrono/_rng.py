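"""Seed management: one global seed fans out to per-stage streams."""

from __future__ import annotations

import hashlib

import numpy as np


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from a global seed and a stage name.

    Uses SHA-256 so the mapping is stable across Python processes and
    platforms (``hash()`` is salted and unsuitable).
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**63)


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage))
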