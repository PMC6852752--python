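"""Exact integer-cent arithmetic.

Audit dollar figures are exact to the cent, and savings tables are additive
over millions of units, so all internal currency is carried as integer cents.
Floating point enters only at presentation time or where a noise model
requires it.
"""

from __future__ import annotations

import re

_DOLLARS_RE = re.compile(r"^\s*-?\$?\s*([\d,]+)(?:\.(\d{1,2}))?\s*$")


def parse_dollars(text: str) -> int:
    """Parse a decimal dollar string (optionally with $ and thousands
    separators) into integer cents."""
    m = _DOLLARS_RE.match(text)
    if m is None:
        raise ValueError(f"not a dollar amount: {text!r}")
    whole = int(m.group(1).replace(",", ""))
    frac = (m.group(2) or "").ljust(2, "0")
    cents = whole * 100 + int(frac)
    return -cents if text.lstrip().startswith("-") else cents


def format_dollars(cents: int) -> str:
    """Render integer cents as a plain decimal string, e.g. 1926 -> '19.26'."""
    sign = "-" if cents < 0 else ""
    cents = abs(cents)
    return f"{sign}{cents // 100}.{cents % 100:02d}"


def div_round_half_up(num: int, den: int) -> int:
    """num / den rounded half away from zero, exact integer arithmetic."""
    if den <= 0:
        raise ZeroDivisionError("denominator must be positive")
    if num >= 0:
        return (2 * num + den) // (2 * den)
    return -((-2 * num + den) // (2 * den))


def cents_to_dollars_half_up(cents: int) -> int:
    """Round integer cents to whole dollars, half away from zero."""
    return div_round_half_up(cents, 100)


def round_half_down(x: float) -> int:
    """Round to nearest integer with exact halves toward zero.

    Matters only for presentation of scenario cells, where the convention
    is fixed by the published tables.
    """
    import math

    if x >= 0:
        return math.ceil(x - 0.5)
    return math.floor(x + 0.5)
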