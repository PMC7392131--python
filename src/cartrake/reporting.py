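"""Percentage formatting shared by report builders.

Rounding mirrors the conventions of the output tables: whole percents in
the recruitment-flow text, two decimals in characteristic tables, one
decimal in purchase-share tables.
"""

from __future__ import annotations

__all__ = ["format_percent"]


def format_percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """``round(100 * numerator / denominator, decimals)`` with validation."""
    if denominator <= 0:
        raise ZeroDivisionError("percentage denominator must be positive")
    value = round(100.0 * numerator / denominator, decimals)
    return float(value) if decimals > 0 else float(int(value))
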