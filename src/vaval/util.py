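"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention of printed tables.

    Python's built-in ``round`` is banker's rounding (round-half-even), which
    does not match how percentages in epidemiological reports are typically
    printed (e.g. 2.5 -> 3, not 2).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
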