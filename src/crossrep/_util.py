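"""Small shared helpers."""

from __future__ import annotations

import hashlib

import numpy as np


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary hashable parts.

    Unlike ``hash()``, this is stable across processes (no string salting),
    so seeded pipelines reproduce byte-identically between runs.
    """
    key = "\x1f".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def stable_rng(*parts) -> np.random.Generator:
    return np.random.default_rng(stable_seed(*parts))
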