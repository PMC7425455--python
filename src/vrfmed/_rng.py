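"""Seed-substream derivation.

All randomness in the package flows from one integer seed.  Stage- or
subject-level generators are derived by hashing string keys into a
``numpy.random.SeedSequence`` so that adding or reordering downstream draws
in one stage never perturbs another stage.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "rng_for"]


def substream(seed: int, *keys: str) -> np.random.SeedSequence:
    """Derive a child SeedSequence from ``seed`` and a path of string keys."""
    words = [int(seed)]
    for key in keys:
        digest = hashlib.sha256(key.encode("utf-8")).digest()
        words.append(int.from_bytes(digest[:8], "little"))
    return np.random.SeedSequence(words)


def rng_for(seed: int, *keys: str) -> np.random.Generator:
    """A ``default_rng`` seeded on the named substream."""
    return np.random.default_rng(substream(seed, *keys))
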