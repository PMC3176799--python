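"""Half-up rounding helpers.

Printed tables in this field round half-up (0.945 → 0.95), whereas
Python's built-in ``round`` is banker's rounding; all table-facing
rounding in pgckit goes through here.  Stored values keep full precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimal places."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
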