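"""Decimal rounding helpers for printed-report values."""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero to ``decimals`` places (report convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, decimals: int = 2) -> float:
    """Truncate toward zero to ``decimals`` places (e.g. 46.666... -> 46.66)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_DOWN))
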