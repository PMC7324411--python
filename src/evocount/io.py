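"""FASTQ/FASTA streaming I/O and Illumina sample discovery.

Input files are demultiplexed paired-end Illumina reads named per the
standard scheme ``sample-name_S#_L00#_R#_001.fastq[.gz]``.  One sample may
be split across several flow-cell lanes; discovery groups files into a
:class:`SampleManifest` keyed by the displayed sample label
(``sample-name_S#``), with each lane holding exactly one R1 and one R2 file.
"""

from __future__ import annotations

import gzip
import os
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

__all__ = [
    "FastqRecord",
    "IlluminaName",
    "SampleManifest",
    "LanePair",
    "NamingError",
    "DiscoveryError",
    "FastqParseError",
    "parse_illumina_name",
    "format_illumina_name",
    "discover_samples",
    "read_fastq",
    "write_fastq",
    "write_fasta",
]

#: Highest Phred score produced by modern Illumina base callers (1.8+).
MAX_QUALITY = 41

ILLUMINA_NAME_RE = re.compile(
    r"^(?P<name>.+)_S(?P<snum>\d+)_L(?P<lane>\d{3})_R(?P<mate>[12])_001"
    r"\.fastq(?P<gz>\.gz)?$"
)


class NamingError(ValueError):
    """A file name does not follow the Illumina naming scheme."""


class DiscoveryError(ValueError):
    """The input directory cannot be resolved into complete sample pairs."""


class FastqParseError(ValueError):
    """A FASTQ stream is malformed (truncated record, seq/qual mismatch...)."""


@dataclass(frozen=True)
class FastqRecord:
    """One sequencing read: identifier, bases and per-base Phred scores."""

    read_id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for read {self.read_id!r}")
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )
        if any(q < 0 or q > MAX_QUALITY for q in self.quality):
            raise ValueError(
                f"read {self.read_id!r}: quality values outside [0, {MAX_QUALITY}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IlluminaName:
    """Parsed components of an Illumina FASTQ file name."""

    sample_name: str
    sample_number: int
    lane: int
    mate: int
    compressed: bool

    @property
    def sample_key(self) -> str:
        """Sample label used for grouping and output naming, e.g. ``test1_S1``."""
        return f"{self.sample_name}_S{self.sample_number}"


@dataclass
class LanePair:
    """R1/R2 paths for one (sample, lane)."""

    lane: int
    r1: Path | None = None
    r2: Path | None = None


@dataclass
class SampleManifest:
    """Mapping sample key -> lanes -> (R1, R2), plus any skipped files."""

    entries: dict[str, list[LanePair]] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return sorted(self.entries)


def parse_illumina_name(filename: str) -> IlluminaName:
    """Parse a base file name against the Illumina scheme.

    The sample-name portion is everything before the final
    ``_S#_L00#_R#_001`` tail, so user sample names may themselves contain
    underscores.
    """
    if os.sep in filename or "/" in filename:
        raise NamingError(f"expected a base file name, got a path: {filename!r}")
    m = ILLUMINA_NAME_RE.match(filename)
    if m is None:
        raise NamingError(
            f"file {filename!r} does not follow the Illumina naming scheme "
            "'sample-name_S#_L00#_R#_001.fastq[.gz]'"
        )
    return IlluminaName(
        sample_name=m.group("name"),
        sample_number=int(m.group("snum")),
        lane=int(m.group("lane")),
        mate=int(m.group("mate")),
        compressed=m.group("gz") is not None,
    )


def format_illumina_name(name: IlluminaName) -> str:
    """Inverse of :func:`parse_illumina_name` (exact round-trip)."""
    ext = ".fastq.gz" if name.compressed else ".fastq"
    return (
        f"{name.sample_name}_S{name.sample_number}_L{name.lane:03d}"
        f"_R{name.mate}_001{ext}"
    )


def discover_samples(input_dir: str | Path, lenient: bool = False) -> SampleManifest:
    """Scan a directory for Illumina-named FASTQ files and pair the mates.

    Files that do not match the naming scheme are a fatal error unless
    ``lenient`` is set, in which case they are recorded in
    ``manifest.skipped``.  A lane missing either mate is always fatal, as is
    a directory containing no matching files.
    """
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise DiscoveryError(f"input directory not found: {input_dir}")

    pairs: dict[tuple[str, int], LanePair] = {}
    skipped: list[str] = []
    matched = 0
    for fname in sorted(p.name for p in input_dir.iterdir() if p.is_file()):
        try:
            parsed = parse_illumina_name(fname)
        except NamingError:
            if lenient:
                skipped.append(fname)
                continue
            raise
        key = (parsed.sample_key, parsed.lane)
        pair = pairs.setdefault(key, LanePair(lane=parsed.lane))
        attr = "r1" if parsed.mate == 1 else "r2"
        if getattr(pair, attr) is not None:
            raise DiscoveryError(
                f"duplicate (sample, lane, mate) entry for {fname!r}"
            )
        setattr(pair, attr, input_dir / fname)
        matched += 1

    if matched == 0:
        raise DiscoveryError(
            f"no files matching the Illumina naming scheme found in {input_dir}"
        )
    for (sample, lane), pair in pairs.items():
        if pair.r1 is None or pair.r2 is None:
            orphan = pair.r1 or pair.r2
            raise DiscoveryError(
                f"sample {sample!r} lane {lane} is missing mate "
                f"{'R2' if pair.r2 is None else 'R1'} "
                f"(unpaired file: {Path(orphan).name})"
            )

    manifest = SampleManifest(skipped=skipped)
    for sample in sorted({s for s, _ in pairs}):
        lanes = sorted(l for s, l in pairs if s == sample)
        manifest.entries[sample] = [pairs[(sample, l)] for l in lanes]
    return manifest


def _open_text(path: str | Path, mode: str) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="ascii")  # type: ignore[return-value]
    return open(path, mode, encoding="ascii")


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream 4-line FASTQ records, transparently gunzipping ``.gz`` paths.

    Phred scores are decoded from the Phred+33 encoding; scores above 41 are
    clamped to 41 with a warning.  Truncated records and seq/qual length
    mismatches raise :class:`FastqParseError` naming the record index.
    """
    with _open_text(path, "r") as fh:
        record_index = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            if any(l == "" for l in lines):
                raise FastqParseError(
                    f"{path}: truncated FASTQ record at index {record_index}"
                )
            header, seq, plus, qual = (l.rstrip("\n") for l in lines)
            if not header.startswith("@") or not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: malformed FASTQ record at index {record_index}"
                )
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: record {record_index} sequence/quality length "
                    f"mismatch ({len(seq)} vs {len(qual)})"
                )
            scores = tuple(b - 33 for b in qual.encode("ascii"))
            if any(q > MAX_QUALITY for q in scores):
                warnings.warn(
                    f"{path}: record {record_index} has Phred scores above "
                    f"{MAX_QUALITY}; clamping",
                    stacklevel=2,
                )
                scores = tuple(min(q, MAX_QUALITY) for q in scores)
            yield FastqRecord(header[1:], seq, scores)
            record_index += 1


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    """Write 4-line Phred+33 FASTQ; gzip output for ``.gz`` paths."""
    with _open_text(path, "w") as fh:
        for rec in records:
            qual = bytes(q + 33 for q in rec.quality).decode("ascii")
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


def write_fasta(records: Iterable[FastqRecord], path: str | Path) -> None:
    """Write records as single-line-per-sequence FASTA."""
    with _open_text(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.read_id}\n{rec.sequence}\n")
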