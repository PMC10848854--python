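"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed tables conventionally do.

    Python's built-in ``round`` uses banker's rounding, which would format
    e.g. 0.125 as 0.12 where a published table prints 0.13.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def dna(codon: str) -> str:
    """RNA codon -> DNA codon (upper-cased)."""
    return codon.upper().replace("U", "T")


def rna(codon: str) -> str:
    """DNA codon -> RNA codon (upper-cased)."""
    return codon.upper().replace("T", "U")
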