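"""Deterministic seed derivation.

All randomness in the pipeline flows from a single integer seed. Stage-level
seeds are derived as

    derive_seed(seed, stage, index) = SHA-256(f"{seed}:{stage}:{index}") mod 2**31

so that re-running any stage in isolation reproduces its in-pipeline output.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(seed: int, stage: str, index: int = 0) -> int:
    """Return a stage-specific 31-bit seed derived from the master seed."""
    digest = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)
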