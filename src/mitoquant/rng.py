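"""Named random substreams.

Every source of randomness in the package derives from one top-level seed
through named substreams, so each stage is reproducible in isolation and
tests can re-draw any stream independently of the code under test.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _name_key(name: str) -> int:
    # stable across processes, unlike hash()
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:8], "big")


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for substream ``name`` of top-level ``seed``.

    The mapping (seed, name) -> stream is deterministic and
    platform-independent.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), _name_key(name)]))
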