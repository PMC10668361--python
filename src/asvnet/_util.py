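"""Shared helpers: seed derivation and logging."""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger("asvnet")


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-specific 32-bit seed from a master seed.

    Stable across runs and platforms (SHA-256 of ``"{master_seed}:{stage}"``),
    so every stochastic pipeline stage gets an independent, reproducible
    stream.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")
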