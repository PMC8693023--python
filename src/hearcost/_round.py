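"""Rounding helpers shared across the cost pipeline.

All monetary outputs are whole US dollars.  Python's built-in ``round`` is
banker's rounding; cost reporting here uses the commercial half-away-from-zero
rule (124.625 -> 125), so it is implemented explicitly.
"""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def pct1(numerator: float, denominator: float) -> float:
    """Percentage to one decimal place, half away from zero.

    ``pct1(32, 155) == 20.6``
    """
    if denominator == 0:
        raise ValueError("percentage denominator is zero")
    return round_half_away(1000.0 * numerator / denominator) / 10.0
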