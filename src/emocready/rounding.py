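"""Display rounding shared by the whole package.

All readiness arithmetic is carried on exact fractions (facility counts over
cohort size); rounding happens once, at display, half away from zero to one
decimal place. Published facility-survey tables round this way, and exact
carry-then-round is what makes pooled rows reproducible from counts.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction

__all__ = ["round1", "fmt1"]

_ONE_DP = Decimal("0.1")


def _to_decimal(x: float | int | Fraction) -> Decimal:
    if isinstance(x, Fraction):
        with localcontext() as ctx:
            ctx.prec = 50
            return Decimal(x.numerator) / Decimal(x.denominator)
    if isinstance(x, int):
        return Decimal(x)
    return Decimal(repr(float(x)))


def round1(x: float | int | Fraction) -> float:
    """Round to 1 decimal, half away from zero. Exact for Fraction input."""
    return float(_to_decimal(x).quantize(_ONE_DP, rounding=ROUND_HALF_UP))


def fmt1(x: float | int | Fraction) -> str:
    """Format at 1 decimal (half away from zero), e.g. ``47.8``."""
    return str(_to_decimal(x).quantize(_ONE_DP, rounding=ROUND_HALF_UP))
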