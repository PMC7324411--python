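# Methods

## Problem and scope

`evocount` turns raw, demultiplexed, paired-end Illumina FASTQ files from an
in vitro selection round into dereplicated count tables. The unit of
analysis is the amplicon insert: the variable region of a selection library
flanked by constant primer regions, sequenced so that the two mates of each
pair overlap and can be merged into one full-length sense-strand sequence.
The pipeline handles multi-lane runs (lanes of one sample are merged before
counting), optional in-frame translation for peptide selections, and exact
read accounting from raw pairs to counted molecules. Quality-based trimming
or filtering is deliberately out of scope; if needed it should be applied
upstream. Single-end, interleaved, and orientation-mixed data are not
supported: the sense strand must be the forward read. Antisense libraries
can be processed by supplying reverse-complemented primers.

## Pair joining

The joiner is a deterministic best-overlap consensus algorithm.

1. The reverse mate is reverse-complemented (qualities reversed).
2. Every overlap length `o` from `min(len_fwd, len_rev)` down to
   `min_overlap` aligns the forward read's `o`-suffix with the
   reverse-complemented mate's `o`-prefix. The score is the mean per-base
   match value: 1 for identical non-N bases, 0.25 when either base is N
   (the expected match rate of a random base), 0 otherwise.
3. The best score wins; ties break toward the **larger** overlap, because
   amplicon libraries sequenced with reads longer than half the template
   are expected to overlap maximally. A best score below `score_threshold`
   means the pair is rejected (`below_threshold`); if no candidate `o`
   exists the status is `no_overlap`.
4. Consensus: outside the overlap each base is copied from its source read.
   Inside it, agreeing bases keep the base with quality
   `min(q_f + q_r, 41)`; disagreements keep the higher-quality base (ties
   favour the forward read) with quality `|q_f − q_r|`.
5. Assembled sequences outside `[min_length, max_length]` are dropped with
   status `length_filtered`.

Only substitutions are tolerated in the overlap — no indel alignment. The
Illumina error profile is substitution-dominated, and this keeps the sweep
`O(L²)` worst case with an early exit on a perfect overlap (the common case
for clean amplicon data). Defaults: `min_overlap = 10`,
`score_threshold = 0.6`, `min_length = 1`, no maximum. These are this
package's own defaults and are echoed in the log header, so every run is
self-describing. They can be changed through the quoted pass-through string
(`-e "-l ... -L ... -o ... -t ..."`); the historical `-d <letters>`
verbosity mask is accepted and ignored with a log note.

Unequal mate lengths are allowed (the sweep uses the shorter read).
Mismatched R1/R2 record counts in one lane are an error.

## Primer extraction

The insert is the subsequence strictly between the forward-primer match and
the reverse-primer match. Primers are supplied as DNA oligo sequences; the
reverse primer is matched as its reverse complement, since the assembled
read is sense-strand. Matching is Hamming (substitution-only), exact by
default; `--primer-mismatches` opts into tolerance. An N in the read always
counts as a mismatch.

Searches are positionally constrained: the forward primer must start within
the first `⌊n/2⌋` positions (leftmost match wins), and the reverse-primer
match must end within the last `⌈n/2⌉` positions (rightmost wins). Random
libraries can contain primer-like substrings; the half-window constraint
prevents such an internal motif from truncating the insert. A supplied
primer that is not found fails that read (`fwd_primer_not_found` /
`rev_primer_not_found`); with a single primer the other boundary is the
read end; with none, the insert is the whole assembled sequence.

## Translation

Translation uses the standard genetic code in frame 0 of the insert — the
library design guarantees the forward primer ends on a codon boundary, so
the extraction cut *is* the frame anchor. Stop codons are rendered `*` and
translation continues through them by default: selections report
full-length variants, and truncating at an internal stop would silently
merge distinct genotypes. `--stop-policy truncate` restores the truncating
behaviour. Codons containing N become `X`; a trailing 1–2 nt remainder is
dropped. Synonymous collapse sums the counts of DNA sequences sharing one
peptide, conserving total molecules exactly.

## Counting and outputs

Dereplication is exact multiset counting (uppercased), with frequencies
derived from integer counts at write time (9 significant digits). Written
order is canonical — count descending, ties lexicographic — so output is
reproducible across platforms and thread counts. Lane merging is
per-sequence count addition and is provably equal to one-pass counting of
the concatenated lanes. Count files carry a three-line header (unique
sequences, total molecules, blank) then `sequence TAB count TAB frequency`
rows; histogram files are `length/unique/reads/fraction` TSV. Parallelism
(`-T`) applies to the per-(sample, lane) join+extract stage only; counting
is a per-sample reduction, and all outputs are byte-invariant to the thread
count.

The log counts read **pairs** (stated in its header), and the accounting
closes exactly: raw = assembled + no_overlap + below_threshold +
length_filtered, and assembled = extracted + primer failures + empty
inserts. Recovery is extracted/raw × 100.

## Synthetic data generator

The generator emulates a typical mRNA-display test library: templates of
the form `fwd_primer + random variable region + rc(rev_primer)`. The
bundled preset uses a 291-nt (97-codon) in-frame variable region flanked by
fixed synthetic 20-nt primers (real designs keep theirs proprietary; the
choice does not affect any pipeline property), sequenced as PE300
overlapping pairs at a default depth of 50,000 pairs per sample with
per-base substitution error 0.003 and Zipf-skewed variant abundances
(exponent 1.0, 100 variants) — the abundance skew a selection round
produces. Variable regions are uniform over A/C/G/T, so internal stop
codons occur at their random expectation; peptide lengths are unaffected
because translation continues through stops.

Reads are cut directly from the template ends (R1 = first 300 nt,
R2 = reverse complement of the last 300 nt) with i.i.d. substitution errors
and qualities drawn from a clipped normal (mean 33, sd 3). Pairs distribute
round-robin across lanes. A fixed seed fixes the full output byte stream.
Not modelled: indels, PCR bias, chimeras, position-dependent quality decay,
orientation flips. Passing tests therefore demonstrate correctness of the
pipeline's algorithms under a substitution-only error model, not robustness
to every artefact of real sequencing runs.

At the preset geometry, the 20-nt primers lie in the single-coverage ends of
the 331-nt template, so with exact primer matching the expected recovery is
about `0.997⁴⁰ ≈ 88.7%` of raw pairs — comfortably above the 85% a
practitioner would expect for clean data, and what the acceptance script
measures empirically.

## Problem sizes and numerical choices

The acceptance script uses 1,000 error-free pairs for the
length-distribution modes (the mode is exact at any depth) and 10,000 noisy
pairs for the recovery estimate, which keeps its sampling error on the
recovery percentage near ±0.6 while remaining quick on one CPU. Frequencies
and histogram fractions must sum to 1 within 1e-9 of rounding; all quality
arithmetic is integer. Degenerate inputs are handled as values, not
crashes: empty FASTQ files yield empty streams, an empty count stream
yields a valid zero-total table with a warning, and every per-read failure
is a tallied status.

## Known limitations

- No indel tolerance anywhere (overlap, primers); an indel-bearing read is
  rejected at assembly or primer matching rather than rescued.
- Exact primer matching by default means recovery degrades as
  `(1 − e)^(2·primer length)` with per-base error rate `e`; mismatch
  tolerance is opt-in.
- The joiner's threshold/overlap defaults are heuristic; for very short or
  low-complexity inserts the chance of a spurious short overlap passing the
  0.6 threshold is non-negligible, and raising `-o`/`-t` is advisable.
- Sample identity is taken from the file name (`name_S#`); inconsistent
  S-numbers for one biological sample produce separate outputs.
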