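"""Half-up decimal rounding for report output.

Internal computation is always full precision; these helpers exist only so
printed grams/proportions/percentages round the way clinical reports do
(0.5 away from zero), rather than banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero; returns float."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def grams(x: float) -> int:
    """Report rounding for gram quantities: nearest integer, half up."""
    return int(round_half_up(x, 0))


def proportion(x: float) -> float:
    """Report rounding for proportions: 3 decimals, half up."""
    return round_half_up(x, 3)


def percent(x: float) -> float:
    """Report rounding for percentages: 1 decimal, half up."""
    return round_half_up(x, 1)
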