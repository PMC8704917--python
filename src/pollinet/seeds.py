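"""Deterministic seed derivation.

A single master seed drives every stochastic stage.  Each stage (and each
replicate within a stage) gets its own 31-bit seed derived from the master
seed and a human-readable tag via BLAKE2b, so stages are independent,
reproducible, and can be re-run in isolation.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int | None, tag: str) -> int:
    """A stable 31-bit seed from (master seed, tag)."""
    if master is None:
        master = 0
    digest = hashlib.blake2b(f"{int(master)}:{tag}".encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def spawn_seeds(master: int | None, n: int, tag: str) -> list[int]:
    """``n`` independent replicate seeds for one stage."""
    return [derive_seed(master, f"{tag}:{i}") for i in range(n)]
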