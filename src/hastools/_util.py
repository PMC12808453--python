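"""Small shared helpers: half-up percent rounding and RNG coercion."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for printed percentages).

    Python's builtin ``round`` is banker's rounding; printed tables in this field
    round 0.5 up, so we go through ``decimal``.
    """
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return v


def percent(n: int, total: int, ndigits: int = 0) -> float:
    """100 * n / total, rounded half-up to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("percent: total must be positive")
    return round_half_up(100.0 * n / total, ndigits)


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
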