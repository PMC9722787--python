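"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), unlike banker's ``round``.

    The input is pre-rounded a few digits below the target to strip binary
    representation noise (e.g. 89.24000000000001) before quantising.
    """
    guarded = round(float(value), ndigits + 6)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(guarded)).quantize(quantum, rounding=ROUND_HALF_UP))
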