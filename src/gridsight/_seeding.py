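"""Deterministic named random substreams.

All randomness in the package flows from a single integer seed.  Each stage
draws from a substream derived from (seed, name, *indices) via SHA-256, so
adding frames or stages never perturbs the draws of the others.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "substream"]


def derive_seed(seed: int, *names: object) -> int:
    """Derive a child seed (< 2**31) from a root seed and a name path."""
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for name in names:
        h.update(b"\x1f")
        h.update(str(name).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def substream(seed: int, *names: object) -> np.random.Generator:
    """A Generator seeded from a named substream of ``seed``."""
    return np.random.default_rng(derive_seed(seed, *names))
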