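"""Small shared helpers: sequence ops and paper-style rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> None:
    """Raise ValueError naming ``name`` if seq contains non-ACGTN characters."""
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"{name}: non-ACGTN characters {sorted(bad)!r} in sequence {seq[:40]!r}"
        )


def percentage(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage rounded half-up to ``ndigits`` decimals (so 0.21094.. -> 21.09).

    Banker's rounding (Python's default) would disagree with the conventional
    half-up style used in sequencing summary tables; Decimal avoids that.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    quantum = Decimal(1).scaleb(-ndigits)
    value = Decimal(numerator) / Decimal(denominator) * 100
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))
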