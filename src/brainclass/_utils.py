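"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Uses the shortest decimal representation of the float so that values
    like 2.675 round to 2.68 rather than falling victim to binary
    representation error.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_sd(x: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Standard deviation with the n-1 denominator (the package-wide convention)."""
    return np.std(x, axis=axis, ddof=1)
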