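"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero at ``decimals`` places (not banker's)."""
    exp = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(exp, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)
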