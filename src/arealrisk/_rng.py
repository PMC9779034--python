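"""Named random-number streams.

All simulation randomness flows from one integer seed.  Each logical
component (covariate scores, measurement noise, spatial effects, counts,
per-chain MCMC streams ...) draws from its own named substream so that
adding or reordering one component never perturbs another's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_rng"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, name)``.

    The name is hashed with CRC-32, which is stable across platforms and
    Python processes (unlike ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept either an integer seed or an existing Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
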