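"""Named random substreams.

All randomness in a run flows from one top-level integer seed.  Each
consumer (cohort generator, replicate harness, Monte-Carlo propagation)
draws from its own named substream so that adding a consumer never
perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator seeded deterministically by (seed, label)."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
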