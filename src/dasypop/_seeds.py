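"""Stable per-stage seed derivation.

One global seed fans out to independent substreams, one per named pipeline
stage, so any stage can be re-run in isolation and still produce the bytes
it produced inside the full run.
"""

from __future__ import annotations

import hashlib

import numpy as np


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic 31-bit seed for a named stage derived from the run seed."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))
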