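"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (output in DNA alphabet)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and map U->T so RNA-alphabet inputs are exact-matchable."""
    return seq.strip().upper().replace("U", "T")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (matches the published two-decimal tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
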