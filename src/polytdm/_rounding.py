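"""Half-up rounding matching the trial tables' formatting."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "printed_decimals"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def printed_decimals(text: str) -> int:
    """Number of decimal places in a printed numeric string."""
    text = text.strip()
    if "." not in text:
        return 0
    return len(text.split(".", 1)[1])
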