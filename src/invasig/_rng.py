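"""Shared random-number-generation policy.

Every stochastic entry point in the package accepts either an integer seed
or a ready-made :class:`numpy.random.Generator`.  All randomness flows
through numpy's PCG64 ``default_rng`` so that a fixed seed yields
bit-identical output across runs and platforms.
"""

from __future__ import annotations

import numpy as np

RngLike = "int | np.random.Generator | None"


def as_generator(seed) -> np.random.Generator:
    """Return a ``numpy.random.Generator`` for ``seed``.

    ``seed`` may be an int, an existing Generator (returned unchanged, so
    callers can thread one generator through a multi-stage run), or None
    (fresh OS entropy).
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a child seed below 2**31 for a derived stream."""
    return int(rng.integers(0, 2**31 - 1))
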