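"""Half-up rounding helpers.

Python's builtin ``round`` uses banker's rounding; the published tables
were produced with conventional half-up rounding, so every displayed
figure in this package goes through these helpers.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round *x* half away from zero at *ndigits* decimal places."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up_int(x: float) -> int:
    """Round *x* half-up to the nearest integer."""
    return int(round_half_up(x, 0))
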