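"""Small numeric helpers shared across modules."""

from __future__ import annotations

from datetime import date
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed tables conventionally do.

    Python's builtin ``round`` is banker's rounding; report cells instead use
    decimal half-up (8.875 -> 8.9 at one decimal).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def completed_years(birth: date, on: date) -> int:
    """Age in completed years on a given date."""
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))
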