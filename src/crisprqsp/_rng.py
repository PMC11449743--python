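"""Named child random streams derived from a single run seed."""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-stage generator: adding a stage never perturbs another."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))
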