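"""Synthetic in vitro selection sequencing datasets.

Generates library designs (constant forward primer + in-frame random
variable region + constant reverse region), abundance-skewed variant pools,
and overlapping paired-end reads with i.i.d. substitution errors, written as
Illumina-named (optionally multi-lane, gzipped) FASTQ files — so every
pipeline stage is testable without external data.

The bundled preset :func:`display_97aa_design` emulates a typical
mRNA-display test library: a 291-nt (97 codon) variable region flanked by
20-nt constant primer regions, sequenced as MiSeq PE300 overlapping pairs
at roughly 50,000 read pairs per sample.  Substitution errors only — no
indels, matching the substitution-dominated Illumina error profile and the
assembler's substitution-only overlap model.
"""

from __future__ import annotations

import argparse
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assemble import reverse_complement
from .io import FastqRecord, write_fastq

__all__ = [
    "LibraryDesign",
    "ReadSimParams",
    "SimulatedSample",
    "display_97aa_design",
    "build_pool",
    "simulate_pairs",
    "write_design_manifest",
    "main",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Preset constant regions (synthetic; the forward primer ends on a codon
#: boundary relative to the variable region, anchoring the reading frame).
PRESET_FWD_PRIMER = "ACGCTGACCTTGGACAAGGC"
PRESET_REV_PRIMER = "GCTTACGGTACGAACCTGCA"

#: Read pairs per sample matching the preset's target sequencing depth.
PRESET_N_PAIRS = 50_000


@dataclass(frozen=True)
class LibraryDesign:
    """A selection library: constant flanks around a random variable region.

    ``rev_primer`` is the reverse-primer oligo; its reverse complement forms
    the 3' constant region of the sense-strand template.  For peptide
    libraries ``variable_region_length`` is a multiple of 3 and the region
    starts in frame immediately after the forward primer.
    """

    fwd_primer: str
    rev_primer: str
    variable_region_length: int = 291
    n_variants: int = 100
    abundance_model: str = "zipf"  # "uniform" or "zipf"
    zipf_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.variable_region_length < 3:
            raise ValueError("variable_region_length must be >= 3")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.abundance_model not in {"uniform", "zipf"}:
            raise ValueError("abundance_model must be 'uniform' or 'zipf'")

    @property
    def template_length(self) -> int:
        return (
            len(self.fwd_primer)
            + self.variable_region_length
            + len(self.rev_primer)
        )


@dataclass(frozen=True)
class ReadSimParams:
    """Sequencing simulation parameters (defaults emulate MiSeq PE300)."""

    n_pairs: int
    read_length: int = 300
    per_base_error_rate: float = 0.003
    quality_mean: int = 33
    quality_sd: float = 3.0
    n_lanes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error_rate < 0.25:
            raise ValueError("per_base_error_rate must be in [0, 0.25)")
        if self.n_pairs < 1 or self.n_lanes < 1 or self.read_length < 1:
            raise ValueError("n_pairs, n_lanes and read_length must be >= 1")


@dataclass
class SimulatedSample:
    """Paths and ground truth for one simulated sample."""

    sample_key: str
    r1_paths: list[Path]
    r2_paths: list[Path]
    templates: list[str]
    weights: list[float]
    fwd_flank: int
    rev_flank: int
    sampled_variants: list[int] = field(default_factory=list)

    @property
    def variable_regions(self) -> list[str]:
        """Variable region of every pool template (primers stripped)."""
        return [t[self.fwd_flank : len(t) - self.rev_flank] for t in self.templates]

    @property
    def sampled_inserts(self) -> list[str]:
        """Variable regions of the sampled templates, in read order."""
        regions = self.variable_regions
        return [regions[i] for i in self.sampled_variants]


def display_97aa_design(n_variants: int = 100) -> LibraryDesign:
    """Preset 97-aa mRNA-display test library (291-nt variable region)."""
    return LibraryDesign(
        fwd_primer=PRESET_FWD_PRIMER,
        rev_primer=PRESET_REV_PRIMER,
        variable_region_length=291,
        n_variants=n_variants,
        abundance_model="zipf",
        zipf_exponent=1.0,
    )


def build_pool(
    design: LibraryDesign, seed: int
) -> list[tuple[str, float]]:
    """Draw the variant pool: sense-strand templates with normalized weights.

    Each template is ``fwd_primer + random variable region +
    reverse_complement(rev_primer)``; weights follow the design's abundance
    model (uniform, or Zipf: weight of rank r proportional to r^-s).
    """
    rng = np.random.default_rng(seed)
    rc_rev = reverse_complement(design.rev_primer)
    templates = []
    for _ in range(design.n_variants):
        region = rng.choice(_BASES, size=design.variable_region_length)
        templates.append(
            design.fwd_primer + region.tobytes().decode("ascii") + rc_rev
        )
    if design.abundance_model == "uniform":
        weights = np.full(design.n_variants, 1.0 / design.n_variants)
    else:
        ranks = np.arange(1, design.n_variants + 1, dtype=float)
        weights = ranks**-design.zipf_exponent
        weights /= weights.sum()
    return list(zip(templates, weights.tolist()))


def _mutate(read: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitutions; each error picks a different base."""
    if rate == 0.0:
        return read
    hits = np.nonzero(rng.random(read.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != read[i]]
        read[i] = rng.choice(choices)
    return read


def simulate_pairs(
    pool: list[tuple[str, float]],
    params: ReadSimParams,
    out_dir: str | Path,
    sample_name: str = "test1",
    sample_number: int = 1,
    compress: bool = False,
    fwd_flank: int = 0,
    rev_flank: int = 0,
) -> SimulatedSample:
    """Simulate read pairs from a pool and write Illumina-named FASTQ files.

    R1 is the first ``read_length`` nt of the sense-strand template (the
    whole template if shorter); R2 is the reverse complement of the last
    ``read_length`` nt.  Pairs are distributed round-robin across lanes.
    The seed fixes the full output byte stream.  ``fwd_flank``/``rev_flank``
    are the constant-region lengths of the design, recorded so ground-truth
    variable regions can be recovered for oracle checks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    templates = [t for t, _ in pool]
    weights = np.array([w for _, w in pool])
    too_long = max(len(t) for t in templates)
    if too_long > 2 * params.read_length:
        raise ValueError(
            f"template length {too_long} exceeds 2 x read_length "
            f"({2 * params.read_length}); mates would not overlap"
        )

    rng = np.random.default_rng(params.seed)
    sample_key = f"{sample_name}_S{sample_number}"
    variant_ids = rng.choice(len(templates), size=params.n_pairs, p=weights)

    lanes: dict[int, tuple[list[FastqRecord], list[FastqRecord]]] = {
        lane: ([], []) for lane in range(1, params.n_lanes + 1)
    }
    for i, vid in enumerate(variant_ids):
        template = templates[vid]
        fwd = template[: params.read_length]
        rev = reverse_complement(template[-params.read_length :])
        fwd_arr = _mutate(
            np.frombuffer(fwd.encode("ascii"), dtype=np.uint8).copy(),
            params.per_base_error_rate,
            rng,
        )
        rev_arr = _mutate(
            np.frombuffer(rev.encode("ascii"), dtype=np.uint8).copy(),
            params.per_base_error_rate,
            rng,
        )
        read_id = f"{sample_key}.{i}"
        quals = []
        for length in (fwd_arr.size, rev_arr.size):
            q = rng.normal(params.quality_mean, params.quality_sd, size=length)
            quals.append(tuple(int(v) for v in np.clip(np.rint(q), 2, 41)))
        lane = (i % params.n_lanes) + 1
        lanes[lane][0].append(
            FastqRecord(read_id, fwd_arr.tobytes().decode("ascii"), quals[0])
        )
        lanes[lane][1].append(
            FastqRecord(read_id, rev_arr.tobytes().decode("ascii"), quals[1])
        )

    ext = ".fastq.gz" if compress else ".fastq"
    r1_paths, r2_paths = [], []
    for lane in range(1, params.n_lanes + 1):
        r1 = out_dir / f"{sample_name}_S{sample_number}_L{lane:03d}_R1_001{ext}"
        r2 = out_dir / f"{sample_name}_S{sample_number}_L{lane:03d}_R2_001{ext}"
        write_fastq(lanes[lane][0], r1)
        write_fastq(lanes[lane][1], r2)
        r1_paths.append(r1)
        r2_paths.append(r2)

    return SimulatedSample(
        sample_key=sample_key,
        r1_paths=r1_paths,
        r2_paths=r2_paths,
        templates=templates,
        weights=[w for _, w in pool],
        fwd_flank=fwd_flank,
        rev_flank=rev_flank,
        sampled_variants=[int(v) for v in variant_ids],
    )


def write_design_manifest(
    sample: SimulatedSample, design: LibraryDesign, path: str | Path
) -> None:
    """Record templates and weights in plain text for oracle checks."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"sample\t{sample.sample_key}\n")
        fh.write(f"fwd_primer\t{design.fwd_primer}\n")
        fh.write(f"rev_primer\t{design.rev_primer}\n")
        fh.write("variant\tweight\ttemplate\n")
        for i, (template, weight) in enumerate(
            zip(sample.templates, sample.weights)
        ):
            fh.write(f"{i}\t{weight:.9g}\t{template}\n")


def main(argv: list[str] | None = None) -> int:
    """CLI entry point for generating a synthetic dataset."""
    parser = argparse.ArgumentParser(
        prog="evocount-simulate",
        description="Generate synthetic paired-end selection sequencing data.",
    )
    parser.add_argument("--out", required=True, help="output directory")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument(
        "--preset",
        default="display-97aa",
        choices=["display-97aa"],
        help="library design preset",
    )
    parser.add_argument("--samples", type=int, default=2)
    parser.add_argument("--pairs", type=int, default=PRESET_N_PAIRS)
    parser.add_argument("--variants", type=int, default=100)
    parser.add_argument("--error-rate", type=float, default=0.003)
    parser.add_argument("--lanes", type=int, default=1)
    parser.add_argument("--gzip", action="store_true")
    args = parser.parse_args(argv)

    design = display_97aa_design(n_variants=args.variants)
    for s in range(1, args.samples + 1):
        pool = build_pool(design, seed=args.seed + s)
        params = ReadSimParams(
            n_pairs=args.pairs,
            per_base_error_rate=args.error_rate,
            n_lanes=args.lanes,
            seed=args.seed + 1000 + s,
        )
        sample = simulate_pairs(
            pool, params, args.out, sample_name=f"test{s}", sample_number=s,
            compress=args.gzip, fwd_flank=len(design.fwd_primer),
            rev_flank=len(design.rev_primer),
        )
        # a subdirectory keeps ground-truth manifests out of strict discovery
        design_dir = Path(args.out) / "design"
        design_dir.mkdir(parents=True, exist_ok=True)
        write_design_manifest(
            sample, design, design_dir / f"{sample.sample_key}.design.tsv"
        )
        print(f"wrote {sample.sample_key}: {args.pairs} pairs, {args.lanes} lane(s)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
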