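"""Small shared numeric helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of printed tables).

    Python's built-in ``round`` is banker's rounding; published coverage
    percentages are conventionally rounded half-up, so 0.5 -> 1, 2.5 -> 3.
    """
    q = Decimal(1).scaleb(-ndigits)
    v = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(v)


def percent(part: int, whole: int) -> int:
    """Integer coverage percentage, rounded half-up (e.g. 35/43 -> 81)."""
    if whole <= 0:
        raise ValueError(f"whole must be positive, got {whole}")
    return int(round_half_up(100.0 * part / whole))
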