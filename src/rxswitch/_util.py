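"""Small shared helpers: exact decimals, ATC syntax, half-up percentage rounding."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

#: ATC codes at level 4 (chemical subgroup, e.g. C10AA) or level 5
#: (substance, e.g. C10AA01): letter, two digits, two letters, optional two digits.
ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}(\d{2})?$")

#: Syntactically valid ATC prefixes of any level (used for exclusion rules,
#: which the formulary literature states at level 3/4, e.g. "A10A").
ATC_PREFIX_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")


def is_valid_atc(code: str) -> bool:
    return bool(ATC_RE.match(code))


def is_valid_atc_prefix(prefix: str) -> bool:
    return bool(ATC_PREFIX_RE.match(prefix))


def as_fraction(x) -> Fraction:
    """Coerce ints, decimal strings ("78.09"), ratio strings ("1/2") and floats
    to an exact Fraction. Floats go through their shortest decimal repr so that
    a literal like 0.01 means exactly 1/100."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, bool):
        raise TypeError("booleans are not amounts")
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(str(x))
    if isinstance(x, Decimal):
        return Fraction(x)
    if isinstance(x, str):
        return Fraction(x.strip())
    raise TypeError(f"cannot interpret {x!r} as an exact amount")


def pct_half_up(count: int | Fraction, total: int | Fraction, digits: int = 1) -> float:
    """Percentage of count/total rounded half-up to ``digits`` decimals.

    Half-up (not banker's) rounding is what clinical performance tables use;
    a column of per-cell-rounded percentages may legitimately sum to 100.1.
    """
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    q = Decimal(1).scaleb(-digits)
    frac = Fraction(count) / Fraction(total) * 100
    d = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def fraction_to_float(x: Fraction) -> float:
    return x.numerator / x.denominator
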