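"""Exact decimal money arithmetic.

All monetary chains in this package are carried as :class:`fractions.Fraction`
so that identities such as ``gap == available - required`` hold exactly: the
only division that produces a repeating decimal (the 37-way fund split) stays
rational until display. Rounding happens once, at presentation, half-up
(half away from zero, the spreadsheet convention the source tables follow).
"""

from __future__ import annotations

from decimal import Decimal
from fractions import Fraction
from numbers import Rational
from typing import Union

Money = Fraction
MoneyLike = Union[int, float, str, Decimal, Fraction]


def as_rational(value: MoneyLike) -> Fraction:
    """Convert a numeric input to an exact :class:`Fraction`.

    Floats are interpreted through their shortest decimal representation
    (``repr``), so ``as_rational(0.63)`` is exactly ``63/100`` rather than the
    nearest binary double. Strings and Decimals convert exactly.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, bool):
        raise TypeError("bool is not a monetary value")
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, Rational):
        return Fraction(value)
    if isinstance(value, Decimal):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(Decimal(repr(value)))
    if isinstance(value, str):
        return Fraction(Decimal(value.replace(",", "").replace("−", "-")))
    raise TypeError(f"cannot interpret {value!r} as a monetary value")


def round_half_up(value: MoneyLike, ndigits: int = 0) -> Union[int, Fraction]:
    """Round half away from zero at ``ndigits`` decimal places.

    Returns an ``int`` when ``ndigits == 0``, otherwise an exact Fraction on
    the requested decimal grid.
    """
    x = as_rational(value)
    scale = Fraction(10) ** ndigits
    scaled = x * scale
    sign = -1 if scaled < 0 else 1
    rounded = sign * ((abs(scaled.numerator) * 2 + scaled.denominator) // (2 * scaled.denominator))
    if ndigits == 0:
        return int(rounded)
    return Fraction(rounded, 1) / scale


def to_float(value: MoneyLike, ndigits: int = 1) -> float:
    """Value as a float rounded half-up at ``ndigits`` (display helper)."""
    return float(round_half_up(value, ndigits))


def fmt_naira(value: MoneyLike) -> str:
    """Whole-Naira display with thousands separators, e.g. ``-739,822,764``."""
    return f"{round_half_up(value):,d}"
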