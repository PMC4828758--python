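"""Nucleotide-alphabet helpers shared across the pipeline.

All internal sequence handling is RNA-space (U, uppercase); FASTQ/FASTA input
in DNA-space is normalized on read.
"""

from __future__ import annotations

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

RNA_ALPHABET = frozenset("ACGU")

#: Allowed base pairs in secondary structure / duplexes (Watson-Crick + wobble).
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)
WC_PAIRS = frozenset([("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")])
GU_PAIRS = frozenset([("G", "U"), ("U", "G")])


def to_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def check_rna(seq: str, *, what: str = "sequence") -> None:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGU characters: {sorted(bad)!r}")


def is_wc(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS


def is_gu(a: str, b: str) -> bool:
    return (a, b) in GU_PAIRS


def can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS
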