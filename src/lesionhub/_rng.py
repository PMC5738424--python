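"""Seed handling.

Every stochastic operation accepts ``seed`` as an int, a
``numpy.random.Generator`` or ``None``.  Pipeline-level master seeds fan
out into independent per-stage / per-subject streams through
``numpy.random.SeedSequence.spawn``, so that adding a stage never
perturbs the draws of another.
"""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed=None) -> np.random.Generator:
    """Return a ``numpy.random.Generator`` for any accepted seed form."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed, n: int) -> list:
    """Derive ``n`` independent generators from a master seed."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif isinstance(seed, np.random.Generator):
        # child streams drawn through the generator itself
        return [np.random.default_rng(s) for s in seed.integers(2**31, size=n)]
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def sub_seed(rng: np.random.Generator) -> int:
    """Draw a 31-bit integer sub-seed (e.g. for an external RNG)."""
    return int(rng.integers(2**31))
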