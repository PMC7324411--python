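"""Dereplicated count tables, lane merging, synonymous collapse, histograms.

A count table lists every distinct sequence in a sample with its absolute
read count and relative frequency — the primary deliverable for downstream
enrichment analysis.  Counts are exact integers; frequencies are derived.
Written ordering is canonical (count-descending, ties lexicographic) so
repeated writes are byte-identical regardless of upstream parallelism.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .extract import translate

__all__ = [
    "CountTable",
    "LengthHistogram",
    "dereplicate",
    "merge_counts",
    "collapse_to_peptides",
    "length_histogram",
    "write_counts",
    "read_counts",
    "write_histo",
]


@dataclass
class CountTable:
    """Sequence -> absolute count, with totals and derived frequencies."""

    entries: Counter = field(default_factory=Counter)
    alphabet: str = "dna"  # "dna" or "peptide"

    @property
    def total_molecules(self) -> int:
        return sum(self.entries.values())

    @property
    def unique_sequences(self) -> int:
        return len(self.entries)

    def frequency(self, seq: str) -> float:
        total = self.total_molecules
        return self.entries[seq] / total if total else 0.0

    def sorted_items(self) -> list[tuple[str, int]]:
        """Canonical order: count descending, ties lexicographic ascending."""
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class LengthHistogram:
    """length -> (unique sequences, total reads, fraction of total reads)."""

    rows: dict[int, tuple[int, int, float]] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(reads for _, reads, _ in self.rows.values())

    def mode(self) -> int | None:
        """Length with the largest read count (ties: smaller length)."""
        if not self.rows:
            return None
        return min(self.rows, key=lambda l: (-self.rows[l][1], l))


def dereplicate(sequences: Iterable[str], alphabet: str = "dna") -> CountTable:
    """Exact multiset counting of sequences, case-normalized to uppercase."""
    table = CountTable(alphabet=alphabet)
    for seq in sequences:
        table.entries[seq.upper()] += 1
    if not table.entries:
        warnings.warn("dereplicating an empty sequence stream", stacklevel=2)
    return table


def merge_counts(tables: Iterable[CountTable]) -> CountTable:
    """Sum per-sequence counts across lanes; totals are additive."""
    tables = list(tables)
    alphabets = {t.alphabet for t in tables}
    if len(alphabets) > 1:
        raise ValueError(f"cannot merge mixed alphabets: {sorted(alphabets)}")
    merged = CountTable(alphabet=tables[0].alphabet if tables else "dna")
    for t in tables:
        merged.entries.update(t.entries)
    return merged


def collapse_to_peptides(
    dna_counts: CountTable, stop_policy: str = "star"
) -> CountTable:
    """Translate each DNA sequence and sum counts of synonymous variants.

    Total molecules are preserved exactly; the number of unique peptides is
    at most the number of unique DNA sequences (genetic-code degeneracy).
    """
    if dna_counts.alphabet != "dna":
        raise ValueError("collapse_to_peptides requires a DNA count table")
    peptides = CountTable(alphabet="peptide")
    for seq, count in dna_counts.entries.items():
        peptides.entries[translate(seq, stop_policy=stop_policy)] += count
    return peptides


def length_histogram(table: CountTable) -> LengthHistogram:
    """Per-length unique-sequence and read totals, ascending by length."""
    uniques: Counter = Counter()
    reads: Counter = Counter()
    for seq, count in table.entries.items():
        uniques[len(seq)] += 1
        reads[len(seq)] += count
    total = table.total_molecules
    hist = LengthHistogram()
    for length in sorted(uniques):
        hist.rows[length] = (
            uniques[length],
            reads[length],
            reads[length] / total if total else 0.0,
        )
    return hist


def write_counts(table: CountTable, path: str | Path) -> None:
    """Write a count file: 3-line header then seq/count/frequency rows.

    Frequencies are printed to 9 significant digits; exactness lives in the
    integer counts.
    """
    total = table.total_molecules
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"number of unique sequences = {table.unique_sequences}\n")
        fh.write(f"total number of molecules = {total}\n\n")
        for seq, count in table.sorted_items():
            fh.write(f"{seq}\t{count}\t{count / total:.9g}\n")


def read_counts(path: str | Path, alphabet: str = "dna") -> CountTable:
    """Parse a count file written by :func:`write_counts` (exact round-trip)."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    try:
        unique = int(lines[0].rsplit("=", 1)[1])
        total = int(lines[1].rsplit("=", 1)[1])
        if lines[2] != "":
            raise IndexError
    except (IndexError, ValueError):
        raise ValueError(f"{path}: malformed count-file header") from None
    table = CountTable(alphabet=alphabet)
    for line in lines[3:]:
        if not line:
            continue
        seq, count, _freq = line.split("\t")
        table.entries[seq] = int(count)
    if table.unique_sequences != unique or table.total_molecules != total:
        raise ValueError(f"{path}: header totals disagree with table body")
    return table


def write_histo(hist: LengthHistogram, path: str | Path) -> None:
    """Write a length-distribution file: header then one row per length."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("length\tunique\treads\tfraction\n")
        for length in sorted(hist.rows):
            unique, reads, fraction = hist.rows[length]
            fh.write(f"{length}\t{unique}\t{reads}\t{fraction:.9g}\n")
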