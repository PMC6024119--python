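"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(value: float | Fraction, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Exact rationals round bit-exactly; floats go through their shortest
    decimal repr to avoid binary representation artefacts.
    """
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100 * numerator/denominator on exact rationals, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(Fraction(100 * numerator, denominator), ndigits)
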