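"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (school rounding), e.g. 0.25 -> 0.3 at 1 dp.

    Printed percentage tables in this field are half-up rounded; banker's rounding
    (Python's built-in) would disagree on exact .5 ties.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, total: float, decimals: int = 1) -> float:
    """count/total as a half-up-rounded percentage; 0.0 when total is 0."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, decimals)


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for a named stream derived from one base seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))
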