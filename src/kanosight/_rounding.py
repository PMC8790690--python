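"""Reporting-boundary rounding.

All arithmetic inside the package runs at full double precision; rounding is
applied only when values are exported or compared against printed tables.
Half-up (away from zero at the midpoint) matches the convention of the
published tables this package reproduces.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero.

    Python's builtin ``round`` uses banker's rounding (0.245 -> 0.24); table
    reporting here needs 0.245 -> 0.25.
    """
    if x is None or x != x:  # pass NaN/absent through
        return float("nan")
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
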