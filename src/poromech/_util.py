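"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Python's built-in ``round`` is banker's rounding; printed percentages in
    clinical tables conventionally round 0.5 up, so summaries use this rule.
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage rounded half-away-from-zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator)
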