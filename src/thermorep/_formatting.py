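"""Display rounding helpers.

Internal values are never rounded; these helpers exist only at the
formatting boundary so printed tables match the one-decimal, half-up
convention of the published summaries.
"""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (spreadsheet-style), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, total: float, ndigits: int = 1) -> float:
    """Percentage of ``part`` in ``total``, display-rounded; 0.0 for empty totals."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * part / total, ndigits)
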