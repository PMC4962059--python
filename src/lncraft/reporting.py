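"""Shared report helpers (rounding conventions)."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed table shares:
    1 dp for superfamily shares, 2 dp for classification shares)."""
    q = Decimal("1") if ndigits == 0 else Decimal("1." + "0" * ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
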