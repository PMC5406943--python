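"""Rounding and p-value formatting conventions used in reports."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "format_p"]


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed clinical tables),
    unlike Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    """Report a p-value to 3 decimals, flooring at ``<0.001``."""
    if p < 0.001:
        return "<0.001"
    return f"{round_half_up(p, 3):.3f}"
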