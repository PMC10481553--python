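"""Small shared helpers: alphabet normalization and half-up rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def normalize_seq(seq: str) -> str:
    """Uppercase a nucleotide string and normalize U residues to T.

    All internal sequences are kept in the DNA alphabet; RNA-specific code
    (folding, duplex scoring) treats T as U.
    """
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the given decimal, as tables print.

    Python's builtin round() is banker's rounding; reported percentages use
    the half-up convention instead.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
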