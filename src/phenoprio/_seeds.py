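"""Stable seed derivation.

Every stochastic step in the pipeline derives its own RNG seed by hashing
the master seed together with stable identifiers (record id, case id, list
size, repetition index ...). This makes each unit of work reproducible in
isolation: adding records or sizes to a run never perturbs the randomness
of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np


def stable_seed(*parts: object) -> int:
    """Derive a 32-bit seed from an arbitrary tuple of hashable parts.

    Uses SHA-256 of the textual representation, so the result is stable
    across processes and Python versions (unlike the builtin ``hash``).
    """
    key = "\x1f".join(str(p) for p in parts).encode("utf-8")
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big")


def rng_for(*parts: object) -> np.random.Generator:
    """A NumPy generator seeded deterministically from ``parts``."""
    return np.random.default_rng(stable_seed(*parts))
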