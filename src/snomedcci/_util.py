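"""Small shared helpers: code normalization and report rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def normalize_code(code: str) -> str:
    """Canonical form of a diagnosis code for comparison.

    Claims extracts disagree on whether ICD codes carry the decimal point
    ("I13.2" vs "I132") and on case; comparisons are done after uppercasing
    and stripping dots while stored codes keep their printed (dotted) form.
    """
    return code.strip().upper().replace(".", "")


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage with half-up rounding, matching printed-table conventions.

    Returns 0.0 for a zero denominator (empty-table rows print 0%).
    """
    if denominator == 0:
        return 0.0
    q = Decimal(str(100.0 * numerator / denominator))
    exp = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding (Python's round() is banker's rounding)."""
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(exp, rounding=ROUND_HALF_UP))
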