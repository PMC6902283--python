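"""Decimal rendering helpers.

Display values are rounded half-up on the decimal representation (the
convention of the reference spectrum tables); internal arithmetic always keeps
full precision.  Ratios are rendered from their integer numerator/denominator
through ``decimal`` so exact ties like 6.875 round predictably instead of
inheriting binary floating-point noise.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal, localcontext

__all__ = ["render_ratio_percent", "round_half_up", "format_fixed"]


def render_ratio_percent(numerator: int, denominator: int, ndigits: int = 2) -> str:
    """Render ``100 * numerator / denominator`` half-up at ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("cannot render a percent with denominator 0")
    with localcontext() as ctx:
        ctx.prec = 40
        value = Decimal(numerator) * 100 / Decimal(denominator)
    return str(value.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round a float half-up on its shortest decimal representation."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def format_fixed(value: float, ndigits: int) -> str:
    """Format with exactly ``ndigits`` decimals, half-up."""
    quantum = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
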