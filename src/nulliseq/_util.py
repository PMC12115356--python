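"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed report tables expect.

    Python's builtin round() is banker's rounding; report tables in this
    field round 0.005 up, so percentages like 12.345 must print 12.35.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator rounded half-up.

    Integer inputs are routed through exact rational arithmetic so the
    rounding decision is never corrupted by float representation.
    """
    if denominator == 0:
        return float("nan")
    if isinstance(numerator, int) and isinstance(denominator, int):
        frac = Fraction(100 * numerator, denominator)
        q = Decimal(1).scaleb(-ndigits)
        d = Decimal(frac.numerator) / Decimal(frac.denominator)
        return float(d.quantize(q, rounding=ROUND_HALF_UP))
    return round_half_up(100.0 * numerator / denominator, ndigits)
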