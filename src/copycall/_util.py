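"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, as printed tables conventionally do.

    Python's builtin ``round`` is banker's rounding; report columns use
    half-up (0.0005 -> 0.001 at 3 decimals).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
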