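"""Small nucleotide-string helpers shared across modules.

Sequences are stored internally in the DNA alphabet (ACGTN); RNA input (U)
is tolerated everywhere and converted on entry. Pairing logic in the
thermodynamic modules works on the RNA alphabet and converts back.
"""

from __future__ import annotations

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

VALID_DNA = frozenset("ACGTN")
VALID_RNA = frozenset("ACGUN")


def to_dna(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and convert T->U."""
    return seq.upper().replace("T", "U")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def check_alphabet(seq: str, *, rna: bool = False, name: str = "sequence") -> str:
    """Validate characters; returns the uppercased sequence.

    Raises ValueError naming the offending sequence on violation.
    """
    up = seq.upper()
    valid = VALID_RNA if rna else VALID_DNA
    bad = set(up) - valid
    if bad:
        raise ValueError(
            f"{name} contains invalid characters {sorted(bad)!r}"
        )
    return up
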