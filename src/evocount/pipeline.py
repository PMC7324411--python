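"""End-to-end pipeline: discover -> join -> extract -> count -> translate.

For every discovered sample the pipeline joins each lane's read pairs,
trims the joined reads to the region between the extraction primers,
merges lanes, dereplicates into DNA (and optionally peptide) count files,
writes length histograms, and appends a per-sample accounting block to a
single run log.  Output tree::

    <output_dir>/
      fastqs/            joined reads per sample (FASTQ)
      fastas/            joined reads per sample (FASTA)
      counts/            DNA count files
      counts.aa/         peptide count files        (translate=True only)
      histos/            nt and aa length distributions
      individual.lanes/  per-lane equivalents       (retain_lanes=True only)
      log.txt

Joining and extraction parallelize over (sample, lane); counting is a
per-sample reduction.  Outputs are byte-identical for any thread count.
Quality-based trimming or filtering is deliberately absent; apply quality
pre-treatment upstream if needed.
"""

from __future__ import annotations

from collections import Counter
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .assemble import AssemblyParams, AssemblyStatus, merge_pair, parse_extra_args
from .counts import (
    CountTable,
    collapse_to_peptides,
    dereplicate,
    length_histogram,
    merge_counts,
    write_counts,
    write_histo,
)
from .extract import ExtractionStatus, PrimerSpec, extract_insert
from .io import (
    FastqRecord,
    LanePair,
    discover_samples,
    read_fastq,
    write_fasta,
    write_fastq,
)

__all__ = ["PipelineConfig", "SampleStats", "RunLog", "run_pipeline"]

DEFAULT_EXTRA_ARGS = "-l 1 -d rbfkms"


@dataclass
class PipelineConfig:
    """Run configuration; defaults mirror the CLI flag defaults."""

    input_dir: str | Path
    output_dir: str | Path = "pipeline.output"
    fwd_primer: str | None = None
    rev_primer: str | None = None
    threads: int = 1
    translate: bool = False
    retain_lanes: bool = False
    extra_assembly_args: str = DEFAULT_EXTRA_ARGS
    primer_mismatches: int = 0
    stop_policy: str = "star"
    overwrite: bool = False
    lenient_naming: bool = False

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValueError("threads must be a positive integer")

    def assembly_params(self) -> tuple[AssemblyParams, list[str]]:
        return parse_extra_args(self.extra_assembly_args)

    def primer_spec(self) -> PrimerSpec:
        return PrimerSpec(
            forward=self.fwd_primer,
            reverse=self.rev_primer,
            max_mismatches=self.primer_mismatches,
        )


@dataclass
class SampleStats:
    """Read accounting for one sample (units: read PAIRS)."""

    sample: str
    raw_pairs: int = 0
    assembled: int = 0
    no_overlap: int = 0
    below_threshold: int = 0
    length_filtered: int = 0
    extracted: int = 0
    fwd_primer_not_found: int = 0
    rev_primer_not_found: int = 0
    empty_insert: int = 0
    unique_dna: int = 0
    total_dna: int = 0
    unique_peptides: int | None = None
    total_peptides: int | None = None

    @property
    def recovery_percent(self) -> float:
        """Extracted pairs / raw pairs x 100 (reads recovered into counts)."""
        return 100.0 * self.extracted / self.raw_pairs if self.raw_pairs else 0.0


@dataclass
class RunLog:
    """Run header plus per-sample accounting; renders to log.txt."""

    config: PipelineConfig
    params: AssemblyParams
    notes: list[str] = field(default_factory=list)
    samples: dict[str, SampleStats] = field(default_factory=dict)

    def render(self) -> str:
        cfg = self.config
        lines = [
            f"evocount v{__version__} run log",
            f"input directory: {cfg.input_dir}",
            f"output directory: {cfg.output_dir}",
            f"forward primer: {cfg.fwd_primer or '(none)'}",
            f"reverse primer: {cfg.rev_primer or '(none)'}",
            f"translate: {cfg.translate}",
            f"retain individual lanes: {cfg.retain_lanes}",
            f"threads: {cfg.threads}",
            (
                "assembly: min_overlap="
                f"{self.params.min_overlap}, score_threshold="
                f"{self.params.score_threshold}, min_length="
                f"{self.params.min_length}, max_length="
                f"{self.params.max_length if self.params.max_length is not None else 'unlimited'}"
            ),
            "raw read unit: read pairs",
        ]
        lines += [f"note: {n}" for n in self.notes]
        for name in sorted(self.samples):
            s = self.samples[name]
            lines += [
                "",
                f"sample: {name}",
                f"  raw read pairs: {s.raw_pairs}",
                f"  assembled pairs: {s.assembled}",
                f"  failed assembly (no overlap): {s.no_overlap}",
                f"  failed assembly (below score threshold): {s.below_threshold}",
                f"  failed assembly (length filtered): {s.length_filtered}",
                f"  extracted pairs: {s.extracted}",
                f"  forward primer not found: {s.fwd_primer_not_found}",
                f"  reverse primer not found: {s.rev_primer_not_found}",
                f"  empty insert: {s.empty_insert}",
                f"  unique DNA sequences: {s.unique_dna}",
                f"  total DNA sequences: {s.total_dna}",
            ]
            if s.unique_peptides is not None:
                lines += [
                    f"  unique peptide sequences: {s.unique_peptides}",
                    f"  total peptide sequences: {s.total_peptides}",
                ]
            lines.append(f"  recovery: {s.recovery_percent:.2f}%")
        return "\n".join(lines) + "\n"


@dataclass
class _LaneResult:
    lane: int
    joined: list[FastqRecord]
    assembly_tally: Counter
    extraction_tally: Counter
    inserts: list[str]


def _process_lane(
    pair: LanePair, params: AssemblyParams, primers: PrimerSpec
) -> _LaneResult:
    """Join and extract one lane's read pairs."""
    assembly_tally: Counter = Counter()
    extraction_tally: Counter = Counter()
    joined: list[FastqRecord] = []
    inserts: list[str] = []
    r1_stream = read_fastq(pair.r1)
    r2_stream = read_fastq(pair.r2)
    for fwd, rev in zip(r1_stream, r2_stream, strict=True):
        outcome = merge_pair(fwd, rev, params)
        assembly_tally[outcome.status] += 1
        if outcome.status is not AssemblyStatus.ASSEMBLED:
            continue
        asm = outcome.payload
        joined.append(FastqRecord(asm.read_id, asm.sequence, asm.quality))
        extraction = extract_insert(asm, primers)
        extraction_tally[extraction.status] += 1
        if extraction.status is ExtractionStatus.EXTRACTED:
            inserts.append(extraction.insert)
    return _LaneResult(pair.lane, joined, assembly_tally, extraction_tally, inserts)


def _write_sample_outputs(
    out: Path,
    stem: str,
    joined: list[FastqRecord],
    dna_table: CountTable,
    config: PipelineConfig,
) -> CountTable | None:
    """Write joined reads, count files and histograms for one sample/lane."""
    write_fastq(joined, out / "fastqs" / f"{stem}.joined.fastq")
    write_fasta(joined, out / "fastas" / f"{stem}.joined.fasta")
    write_counts(dna_table, out / "counts" / f"{stem}.counts.txt")
    write_histo(length_histogram(dna_table), out / "histos" / f"{stem}.histo.txt")
    if not config.translate:
        return None
    aa_table = collapse_to_peptides(dna_table, stop_policy=config.stop_policy)
    write_counts(aa_table, out / "counts.aa" / f"{stem}.counts.aa.txt")
    write_histo(length_histogram(aa_table), out / "histos" / f"{stem}.aa.histo.txt")
    return aa_table


def _make_output_tree(root: Path, config: PipelineConfig) -> None:
    if root.exists() and any(root.iterdir()) and not config.overwrite:
        raise FileExistsError(
            f"output directory {root} exists and is not empty "
            "(pass overwrite=True / --overwrite to replace its contents)"
        )
    subdirs = ["fastqs", "fastas", "counts", "histos"]
    if config.translate:
        subdirs.append("counts.aa")
    for sub in subdirs:
        (root / sub).mkdir(parents=True, exist_ok=True)
    if config.retain_lanes:
        for sub in subdirs:
            (root / "individual.lanes" / sub).mkdir(parents=True, exist_ok=True)


def run_pipeline(config: PipelineConfig) -> RunLog:
    """Run the full pipeline; returns the run log (also written to log.txt)."""
    params, notes = config.assembly_params()
    primers = config.primer_spec()
    manifest = discover_samples(config.input_dir, lenient=config.lenient_naming)
    out = Path(config.output_dir)
    _make_output_tree(out, config)

    log = RunLog(config=config, params=params, notes=list(notes))
    for fname in manifest.skipped:
        log.notes.append(f"skipped non-matching file: {fname}")

    # One task per (sample, lane); executor map preserves submission order,
    # so downstream reductions are thread-count invariant.
    tasks = [
        (sample, pair)
        for sample in manifest.samples
        for pair in manifest.entries[sample]
    ]
    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(
                pool.map(lambda t: _process_lane(t[1], params, primers), tasks)
            )
    else:
        results = [_process_lane(pair, params, primers) for _, pair in tasks]

    by_sample: dict[str, list[_LaneResult]] = {}
    for (sample, _), result in zip(tasks, results):
        by_sample.setdefault(sample, []).append(result)

    for sample in manifest.samples:
        lane_results = by_sample[sample]
        stats = SampleStats(sample=sample)
        lane_tables: list[CountTable] = []
        joined_all: list[FastqRecord] = []
        for res in lane_results:
            stats.raw_pairs += sum(res.assembly_tally.values())
            stats.assembled += res.assembly_tally[AssemblyStatus.ASSEMBLED]
            stats.no_overlap += res.assembly_tally[AssemblyStatus.NO_OVERLAP]
            stats.below_threshold += res.assembly_tally[AssemblyStatus.BELOW_THRESHOLD]
            stats.length_filtered += res.assembly_tally[AssemblyStatus.LENGTH_FILTERED]
            stats.extracted += res.extraction_tally[ExtractionStatus.EXTRACTED]
            stats.fwd_primer_not_found += res.extraction_tally[
                ExtractionStatus.FWD_PRIMER_NOT_FOUND
            ]
            stats.rev_primer_not_found += res.extraction_tally[
                ExtractionStatus.REV_PRIMER_NOT_FOUND
            ]
            stats.empty_insert += res.extraction_tally[ExtractionStatus.EMPTY_INSERT]
            lane_table = dereplicate(res.inserts) if res.inserts else CountTable()
            lane_tables.append(lane_table)
            joined_all.extend(res.joined)
            if config.retain_lanes:
                _write_sample_outputs(
                    out / "individual.lanes",
                    f"{sample}_L{res.lane:03d}",
                    res.joined,
                    lane_table,
                    config,
                )

        dna_table = merge_counts(lane_tables)
        stats.unique_dna = dna_table.unique_sequences
        stats.total_dna = dna_table.total_molecules
        aa_table = _write_sample_outputs(out, sample, joined_all, dna_table, config)
        if aa_table is not None:
            stats.unique_peptides = aa_table.unique_sequences
            stats.total_peptides = aa_table.total_molecules
        log.samples[sample] = stats

    (out / "log.txt").write_text(log.render(), encoding="utf-8")
    return log
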