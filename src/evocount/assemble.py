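"""Paired-end read joining by best-overlap consensus.

Each read pair is merged into a single contiguous sequence: the reverse mate
is reverse-complemented onto the sense strand, every candidate overlap length
is scored by the fraction of matching bases, and the best-scoring overlap
(ties broken toward the longer overlap, the geometry expected for amplicons
with designed full overlap) is accepted if it meets the score threshold.
Disagreements inside the overlap are resolved toward the higher-quality base.
Substitutions only: no indel alignment inside the overlap, consistent with
the substitution-dominated Illumina error model.
"""

from __future__ import annotations

import enum
import shlex
from dataclasses import dataclass

import numpy as np

from .io import MAX_QUALITY, FastqRecord

__all__ = [
    "AssemblyParams",
    "AssembledRead",
    "AssemblyOutcome",
    "AssemblyStatus",
    "reverse_complement",
    "score_overlap",
    "merge_pair",
    "parse_extra_args",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Score contribution of an overlap position where either base is N: the
#: expected match fraction of a uniformly random base.
N_MATCH_SCORE = 0.25


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (N maps to N)."""
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(invalid)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AssemblyParams:
    """Joining parameters.

    min_overlap      smallest overlap length considered (bases)
    score_threshold  minimum accepted match fraction in [0, 1]
    min_length       shortest assembled sequence kept (the ``-l`` flag)
    max_length       longest assembled sequence kept, None = unlimited (``-L``)
    """

    min_overlap: int = 10
    score_threshold: float = 0.6
    min_length: int = 1
    max_length: int | None = None

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


class AssemblyStatus(str, enum.Enum):
    ASSEMBLED = "assembled"
    NO_OVERLAP = "no_overlap"
    BELOW_THRESHOLD = "below_threshold"
    LENGTH_FILTERED = "length_filtered"


@dataclass(frozen=True)
class AssembledRead:
    read_id: str
    sequence: str
    quality: tuple[int, ...]
    overlap_length: int
    overlap_score: float


@dataclass(frozen=True)
class AssemblyOutcome:
    status: AssemblyStatus
    payload: AssembledRead | None = None


def score_overlap(fwd_suffix: str, rev_prefix: str) -> float:
    """Match fraction of two equal-length overlap windows.

    Per position: 1 for identical non-N bases, ``N_MATCH_SCORE`` if either
    base is N, 0 otherwise; averaged over the window.
    """
    if len(fwd_suffix) != len(rev_prefix) or not fwd_suffix:
        raise ValueError("overlap windows must have equal non-zero length")
    total = 0.0
    for a, b in zip(fwd_suffix, rev_prefix):
        if a == "N" or b == "N":
            total += N_MATCH_SCORE
        elif a == b:
            total += 1.0
    return total / len(fwd_suffix)


def merge_pair(
    fwd: FastqRecord, rev: FastqRecord, params: AssemblyParams | None = None
) -> AssemblyOutcome:
    """Join one read pair; every failure mode is a status, not an exception.

    The reverse mate is reverse-complemented (qualities reversed); overlap
    lengths from ``min(len(fwd), len(rev))`` down to ``min_overlap`` are
    scored and the best score wins, ties to the larger overlap.  Consensus
    within the overlap: agreeing bases get quality ``min(q_f + q_r, 41)``;
    disagreeing positions keep the higher-quality base (tie: forward's) with
    quality ``|q_f - q_r|``.
    """
    params = params or AssemblyParams()
    rc_seq = reverse_complement(rev.sequence)
    rc_qual = rev.quality[::-1]

    max_o = min(len(fwd), len(rev))
    if max_o < params.min_overlap:
        return AssemblyOutcome(AssemblyStatus.NO_OVERLAP)

    # Vectorized sweep; per-position scores are exact binary fractions, so
    # this agrees bit-for-bit with score_overlap on the same windows.
    f_arr = np.frombuffer(fwd.sequence.encode("ascii"), dtype=np.uint8)
    r_arr = np.frombuffer(rc_seq.encode("ascii"), dtype=np.uint8)
    n_code = ord("N")
    best_o = 0
    best_score = -1.0
    for o in range(max_o, params.min_overlap - 1, -1):
        a = f_arr[len(f_arr) - o :]
        b = r_arr[:o]
        n_mask = (a == n_code) | (b == n_code)
        score = (int(((a == b) & ~n_mask).sum()) + N_MATCH_SCORE * int(n_mask.sum())) / o
        if score > best_score:  # strict: first (largest) o wins ties
            best_score = score
            best_o = o
        if best_score == 1.0:
            break
    if best_score < params.score_threshold:
        return AssemblyOutcome(AssemblyStatus.BELOW_THRESHOLD)

    o = best_o
    head_seq = fwd.sequence[: len(fwd) - o]
    head_qual = fwd.quality[: len(fwd) - o]
    tail_seq = rc_seq[o:]
    tail_qual = rc_qual[o:]

    mid_seq: list[str] = []
    mid_qual: list[int] = []
    for i in range(o):
        bf, bq = fwd.sequence[len(fwd) - o + i], fwd.quality[len(fwd) - o + i]
        rf, rq = rc_seq[i], rc_qual[i]
        if bf == rf:
            mid_seq.append(bf)
            mid_qual.append(min(bq + rq, MAX_QUALITY))
        elif bq >= rq:
            mid_seq.append(bf)
            mid_qual.append(abs(bq - rq))
        else:
            mid_seq.append(rf)
            mid_qual.append(abs(bq - rq))

    sequence = head_seq + "".join(mid_seq) + tail_seq
    quality = tuple(head_qual) + tuple(mid_qual) + tuple(tail_qual)
    if len(sequence) < params.min_length or (
        params.max_length is not None and len(sequence) > params.max_length
    ):
        return AssemblyOutcome(AssemblyStatus.LENGTH_FILTERED)
    return AssemblyOutcome(
        AssemblyStatus.ASSEMBLED,
        AssembledRead(fwd.read_id, sequence, quality, o, best_score),
    )


def parse_extra_args(extra: str) -> tuple[AssemblyParams, list[str]]:
    """Parse the quoted assembler pass-through string (default "-l 1 -d rbfkms").

    Recognized tokens: ``-l <int>`` minimum length, ``-L <int>`` maximum
    length, ``-o <int>`` minimum overlap, ``-t <float>`` score threshold,
    ``-d <letters>`` log-verbosity mask (accepted, no computational effect).
    Returns the parameters plus warnings for ignored tokens; unrecognized
    tokens raise ValueError listing what is supported.
    """
    tokens = shlex.split(extra)
    kwargs: dict = {}
    notes: list[str] = []
    i = 0
    while i < len(tokens):
        flag = tokens[i]
        if flag not in {"-l", "-L", "-o", "-t", "-d"}:
            raise ValueError(
                f"unrecognized assembler token {flag!r}; supported: "
                "-l <min length>, -L <max length>, -o <min overlap>, "
                "-t <score threshold>, -d <log letters>"
            )
        if i + 1 >= len(tokens):
            raise ValueError(f"assembler token {flag!r} is missing its value")
        value = tokens[i + 1]
        i += 2
        if flag == "-l":
            kwargs["min_length"] = int(value)
        elif flag == "-L":
            kwargs["max_length"] = int(value)
        elif flag == "-o":
            kwargs["min_overlap"] = int(value)
        elif flag == "-t":
            kwargs["score_threshold"] = float(value)
        else:  # -d: verbosity mask only
            notes.append(f"ignoring log-verbosity mask '-d {value}'")
    return AssemblyParams(**kwargs), notes
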