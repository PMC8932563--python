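"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Python's built-in ``round`` is banker's rounding; census tables are
    presented with half-away-from-zero rounding (-5.55 -> -6, 73.9 -> 74).
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def round_to_nearest(x: float, base: int) -> int:
    """Round ``x`` to the nearest multiple of ``base`` (ties away from zero)."""
    if base <= 0:
        raise ValueError("base must be a positive integer")
    return round_half_away(x / base) * base
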