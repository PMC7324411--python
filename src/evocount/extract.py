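"""Primer-based insert extraction and in-frame translation.

Assembled reads are trimmed to the region strictly between the user-supplied
extraction primers.  The forward primer is searched on the sense strand near
the 5' end; the reverse primer is supplied as the primer oligo and therefore
searched as its reverse complement near the 3' end.  The positional
half-window restriction keeps a primer-like motif inside the variable region
from truncating the insert.

The forward-primer boundary is the translation frame anchor: library designs
place the end of the forward primer on a codon boundary, so translation of
the extracted insert starts at frame 0.  With no primers supplied the full
assembled sequence is the insert and translation starts at its first base.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .assemble import AssembledRead, reverse_complement

__all__ = [
    "PrimerSpec",
    "ExtractionOutcome",
    "ExtractionStatus",
    "find_primer",
    "extract_insert",
    "translate",
    "CODON_TABLE",
]

# Standard genetic code; '*' marks stop codons.
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class PrimerSpec:
    """Extraction primers (DNA, A/C/G/T only); at least one enables trimming.

    ``reverse`` is the reverse-primer oligo sequence; its reverse complement
    is what appears on the assembled sense strand.  ``max_mismatches`` is the
    Hamming tolerance per primer (default exact matching).
    """

    forward: str | None = None
    reverse: str | None = None
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            if primer is not None and (not primer or set(primer) - set("ACGT")):
                raise ValueError(
                    f"primer must be a non-empty DNA string over ACGT: {primer!r}"
                )
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @property
    def any_primer(self) -> bool:
        return self.forward is not None or self.reverse is not None


class ExtractionStatus(str, enum.Enum):
    EXTRACTED = "extracted"
    FWD_PRIMER_NOT_FOUND = "fwd_primer_not_found"
    REV_PRIMER_NOT_FOUND = "rev_primer_not_found"
    EMPTY_INSERT = "empty_insert"


@dataclass(frozen=True)
class ExtractionOutcome:
    status: ExtractionStatus
    insert: str | None = None


def _hamming_at(seq: str, pattern: str, start: int) -> int:
    """Mismatch count of pattern laid on seq at start; N in seq mismatches."""
    return sum(
        1
        for i, p in enumerate(pattern)
        if seq[start + i] != p or seq[start + i] == "N"
    )


def find_primer(
    seq: str,
    primer: str,
    end: str,
    max_mismatches: int = 0,
) -> tuple[int, int] | None:
    """Locate a primer in an assembled sense-strand sequence.

    ``end='five_prime'``: leftmost occurrence of ``primer`` whose start lies
    within the first ``len(seq) // 2`` positions.  ``end='three_prime'``:
    rightmost occurrence of ``reverse_complement(primer)`` whose last base
    lies within the final ``ceil(len(seq) / 2)`` positions.  Returns
    ``(start, stop)`` offsets (half-open) or None.
    """
    n = len(seq)
    if len(primer) >= n:
        return None
    if end == "five_prime":
        pattern = primer
        starts = range(0, min(n // 2, n - len(pattern) + 1))
    elif end == "three_prime":
        pattern = reverse_complement(primer)
        first_allowed_end = n - (n + 1) // 2  # last ceil(n/2) positions
        starts = range(
            n - len(pattern), max(first_allowed_end - len(pattern) + 1, 0) - 1, -1
        )
    else:
        raise ValueError("end must be 'five_prime' or 'three_prime'")
    for start in starts:
        if _hamming_at(seq, pattern, start) <= max_mismatches:
            return (start, start + len(pattern))
    return None


def extract_insert(
    asm: AssembledRead | str, primers: PrimerSpec
) -> ExtractionOutcome:
    """Trim an assembled read to the region strictly between the primers.

    A supplied primer is required: if not found, the corresponding
    ``*_primer_not_found`` status is returned.  With one primer the other
    boundary is the sequence end; with none the insert is the full sequence.
    Overlapping or abutting primer matches yield ``empty_insert``.
    """
    seq = asm if isinstance(asm, str) else asm.sequence
    start, stop = 0, len(seq)
    if primers.forward is not None:
        hit = find_primer(seq, primers.forward, "five_prime", primers.max_mismatches)
        if hit is None:
            return ExtractionOutcome(ExtractionStatus.FWD_PRIMER_NOT_FOUND)
        start = hit[1]
    if primers.reverse is not None:
        hit = find_primer(seq, primers.reverse, "three_prime", primers.max_mismatches)
        if hit is None:
            return ExtractionOutcome(ExtractionStatus.REV_PRIMER_NOT_FOUND)
        stop = hit[0]
    if start >= stop:
        return ExtractionOutcome(ExtractionStatus.EMPTY_INSERT)
    return ExtractionOutcome(ExtractionStatus.EXTRACTED, seq[start:stop])


def translate(dna: str, stop_policy: str = "star") -> str:
    """Translate frame-0 DNA with the standard genetic code.

    Stop codons become ``'*'`` and translation continues through them
    (``stop_policy='star'``, the default, so full-length variants that differ
    after an internal stop stay distinct) or end the peptide
    (``stop_policy='truncate'``).  Any codon containing N becomes ``'X'``;
    a trailing 1-2 nt remainder is dropped.  Total and deterministic on
    {A,C,G,T,N}*; input shorter than one codon gives an empty peptide.
    """
    if stop_policy not in {"star", "truncate"}:
        raise ValueError("stop_policy must be 'star' or 'truncate'")
    peptide: list[str] = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        aa = "X" if "N" in codon else CODON_TABLE[codon]
        if aa == "*" and stop_policy == "truncate":
            break
        peptide.append(aa)
    return "".join(peptide)
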