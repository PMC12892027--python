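"""Shared numeric helpers: half-up rounding and derived RNG streams."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

# Named substream offsets so each module draws from an independent stream
# derived from one top-level seed and stays reproducible in isolation.
STREAM_POPULATION = 11
STREAM_TRAITS = 12
STREAM_IDENTITY = 13
STREAM_RECRUITMENT = 21
STREAM_FRAUD = 22
STREAM_RESPONSES = 23
STREAM_BOOTSTRAP = 31


def derived_rng(seed: int, stream: int) -> np.random.Generator:
    """Generator for a named substream of a top-level seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for all printed
    percentages and for integerizing imputed degrees), unlike banker's
    rounding in built-in round()."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, 1)
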