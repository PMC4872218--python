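"""Half-up rounding on exact rationals.

The printed tables round ties upward (e.g. 37.5% -> 38%), so banker's
rounding (Python's built-in ``round``) would not reproduce them.  All
rounding here goes through :class:`fractions.Fraction` to keep the
decision exact; ties go toward +infinity.
"""

from __future__ import annotations

import math
from fractions import Fraction
from numbers import Rational


def round_half_up_int(value) -> int:
    """Round to the nearest integer, ties toward +infinity."""
    x = value if isinstance(value, Rational) else Fraction(value)
    return math.floor(x + Fraction(1, 2))


def round_half_up(value, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals, ties toward +infinity."""
    x = value if isinstance(value, Rational) else Fraction(value)
    scale = Fraction(10) ** ndigits
    return float(math.floor(x * scale + Fraction(1, 2)) / scale)
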