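"""Overlap scoring, pair merging, and the assembler parameter surface."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evocount.assemble import (
    AssemblyParams,
    AssemblyStatus,
    merge_pair,
    parse_extra_args,
    reverse_complement,
    score_overlap,
)
from evocount.io import FastqRecord

from conftest import random_dna

dna = st.text(alphabet="ACGTN", min_size=1, max_size=60)


def q40(seq: str) -> FastqRecord:
    return FastqRecord("r", seq, (40,) * len(seq))


def make_pair(template: str, read_len: int):
    """Cut an error-free overlapping pair from a sense-strand template."""
    fwd = q40(template[:read_len])
    rev = q40(reverse_complement(template[-read_len:]))
    return fwd, rev


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected", [("ACGT", "ACGT"), ("AACGN", "NCGTT"), ("A", "T")]
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_rejects_non_iupac(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            reverse_complement("ACGU")


class TestScoreOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 1.0),
            ("ACGT", "ACGA", 0.75),
            ("ANGT", "ACGT", (1 + 0.25 + 1 + 1) / 4),  # 0.8125
            ("NNNN", "NNNN", 0.25),
        ],
    )
    def test_match_fraction(self, a, b, expected):
        assert score_overlap(a, b) == expected

    def test_length_mismatch_is_contract_violation(self):
        with pytest.raises(ValueError):
            score_overlap("ACG", "AC")

    @given(dna.filter(lambda s: "N" not in s), st.data())
    def test_n_substitution_shifts_score_by_quarter_minus_match(self, seq, data):
        # replacing one overlap base by N changes the score by (0.25 - m_i)/o
        other = data.draw(
            st.text(alphabet="ACGT", min_size=len(seq), max_size=len(seq))
        )
        i = data.draw(st.integers(0, len(seq) - 1))
        base = score_overlap(seq, other)
        m_i = 1.0 if seq[i] == other[i] else 0.0
        mutated = seq[:i] + "N" + seq[i + 1 :]
        assert score_overlap(mutated, other) == pytest.approx(
            base + (0.25 - m_i) / len(seq), abs=1e-12
        )


class TestMergePair:
    def test_template_example(self):
        # template "ACGTACGTTTT": fwd = first 8 nt, rev = rc of last 8 nt
        template = "ACGTACGTTTT"
        fwd, rev = make_pair(template, 8)
        outcome = merge_pair(fwd, rev, AssemblyParams(min_overlap=3))
        assert outcome.status is AssemblyStatus.ASSEMBLED
        assert outcome.payload.sequence == template
        assert outcome.payload.overlap_length == 5
        assert outcome.payload.overlap_score == 1.0
        # brute-force argmax over all candidate overlaps confirms o=5
        rc_rev = reverse_complement(rev.sequence)
        scores = {
            o: score_overlap(fwd.sequence[-o:], rc_rev[:o]) for o in range(3, 9)
        }
        assert max(scores.items(), key=lambda kv: (kv[1], kv[0]))[0] == 5

    def test_identical_mates_full_overlap_fixed_point(self):
        seq = "ACGTTGCAACGTTGCA"
        fwd = q40(seq)
        rev = q40(reverse_complement(seq))
        outcome = merge_pair(fwd, rev, AssemblyParams(min_overlap=3))
        assert outcome.status is AssemblyStatus.ASSEMBLED
        assert outcome.payload.sequence == seq
        assert outcome.payload.overlap_length == len(seq)

    def test_disjoint_reads_essentially_never_assemble(self, rng):
        # unrelated 50-mers: a rare chance overlap at the minimum length can
        # scrape past the 0.6 threshold, but nearly all pairs must fail and
        # no spurious join can look like a real amplicon overlap
        statuses = []
        for _ in range(20):
            fwd = q40(random_dna(rng, 50))
            rev = q40(random_dna(rng, 50))
            statuses.append(merge_pair(fwd, rev, AssemblyParams()))
        failed = [
            s
            for s in statuses
            if s.status
            in (AssemblyStatus.NO_OVERLAP, AssemblyStatus.BELOW_THRESHOLD)
        ]
        assert len(failed) >= 18
        for outcome in statuses:
            if outcome.status is AssemblyStatus.ASSEMBLED:
                # chance overlaps are weak, never amplicon-like identity
                assert outcome.payload.overlap_score < 0.7

    def test_reads_shorter_than_min_overlap_give_no_overlap(self):
        outcome = merge_pair(q40("ACGT"), q40("ACGT"), AssemblyParams(min_overlap=10))
        assert outcome.status is AssemblyStatus.NO_OVERLAP

    def test_template_reconstruction_sweep_read_length_30(self, rng):
        # error-free pairs cut from a template with every true overlap o*
        params = AssemblyParams(min_overlap=5)
        read_len = 30
        for true_overlap in range(params.min_overlap, read_len + 1):
            template = random_dna(rng, 2 * read_len - true_overlap)
            fwd, rev = make_pair(template, read_len)
            outcome = merge_pair(fwd, rev, params)
            assert outcome.status is AssemblyStatus.ASSEMBLED
            assert outcome.payload.sequence == template, f"o*={true_overlap}"
            assert outcome.payload.overlap_length == true_overlap

    def test_reported_score_matches_reference_scorer(self, rng):
        for _ in range(20):
            template = random_dna(rng, 45)
            fwd, rev = make_pair(template, 30)
            # inject a substitution so the overlap is imperfect
            seq = list(fwd.sequence)
            seq[20] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[20]]
            fwd = q40("".join(seq))
            outcome = merge_pair(fwd, rev, AssemblyParams(min_overlap=5))
            if outcome.status is not AssemblyStatus.ASSEMBLED:
                continue
            o = outcome.payload.overlap_length
            rc_rev = reverse_complement(rev.sequence)
            assert outcome.payload.overlap_score == score_overlap(
                fwd.sequence[-o:], rc_rev[:o]
            )

    def test_threshold_monotonicity(self, rng):
        pairs = []
        for i in range(40):
            template = random_dna(rng, 45)
            fwd, rev = make_pair(template, 30)
            if i % 2:  # corrupt half the forward reads heavily
                fwd = q40(random_dna(rng, 30))
            pairs.append((fwd, rev))
        counts = []
        for threshold in (0.0, 0.3, 0.6, 0.9, 1.0):
            params = AssemblyParams(min_overlap=5, score_threshold=threshold)
            counts.append(
                sum(
                    merge_pair(f, r, params).status is AssemblyStatus.ASSEMBLED
                    for f, r in pairs
                )
            )
        assert counts == sorted(counts, reverse=True)

    def test_consensus_prefers_higher_quality_base(self):
        # disagreement in the overlap: higher-quality base wins, qual |qf-qr|
        template = "ACGTACGTGCA"
        fwd = FastqRecord("r", template[:8], (40,) * 7 + (10,))
        rev_seq = reverse_complement(template[3:])
        rev = FastqRecord("r", rev_seq, (40,) * 8)
        # mutate fwd's last base (template pos 7, inside the overlap)
        mutated = fwd.sequence[:7] + ("A" if fwd.sequence[7] != "A" else "C")
        fwd = FastqRecord("r", mutated, fwd.quality)
        outcome = merge_pair(fwd, rev, AssemblyParams(min_overlap=3))
        assert outcome.status is AssemblyStatus.ASSEMBLED
        assert outcome.payload.sequence == template  # rev's Q40 base wins
        assert outcome.payload.quality[7] == 30  # |10 - 40|

    def test_agreement_quality_caps_at_41(self):
        template = "ACGTACGT"
        fwd, rev = make_pair(template, 8)
        outcome = merge_pair(fwd, rev, AssemblyParams(min_overlap=3))
        assert outcome.status is AssemblyStatus.ASSEMBLED
        assert all(q == 41 for q in outcome.payload.quality)

    @settings(max_examples=60, deadline=None)
    @given(
        template=st.text(alphabet="ACGTN", min_size=12, max_size=40),
        qf=st.integers(0, 41),
        qr=st.integers(0, 41),
    )
    def test_consensus_quality_bounds(self, template, qf, qr):
        fwd = FastqRecord("r", template[:10], (qf,) * 10)
        rev = FastqRecord(
            "r", reverse_complement(template[-10:]), (qr,) * 10
        )
        outcome = merge_pair(fwd, rev, AssemblyParams(min_overlap=3, score_threshold=0))
        if outcome.status is AssemblyStatus.ASSEMBLED:
            assert all(0 <= q <= 41 for q in outcome.payload.quality)
            assert len(outcome.payload.sequence) == 20 - outcome.payload.overlap_length

    def test_length_filter(self):
        template = "ACGTACGTTTT"
        fwd, rev = make_pair(template, 8)
        params = AssemblyParams(min_overlap=3, max_length=10)
        assert (
            merge_pair(fwd, rev, params).status is AssemblyStatus.LENGTH_FILTERED
        )
        params = AssemblyParams(min_overlap=3, min_length=12)
        assert (
            merge_pair(fwd, rev, params).status is AssemblyStatus.LENGTH_FILTERED
        )


class TestParamSurface:
    def test_default_passthrough_string(self):
        params, notes = parse_extra_args("-l 1 -d rbfkms")
        assert params == AssemblyParams(min_length=1)
        assert notes == ["ignoring log-verbosity mask '-d rbfkms'"]

    def test_max_length_token(self):
        params, _ = parse_extra_args("-L 50")
        assert params.max_length == 50

    def test_overlap_and_threshold_tokens(self):
        params, _ = parse_extra_args("-o 5 -t 0.8")
        assert params.min_overlap == 5 and params.score_threshold == 0.8

    def test_unrecognized_token_lists_supported(self):
        with pytest.raises(ValueError, match="supported"):
            parse_extra_args("-z 3")

    def test_missing_value(self):
        with pytest.raises(ValueError, match="missing its value"):
            parse_extra_args("-l")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_overlap": 0},
            {"score_threshold": 1.5},
            {"min_length": 0},
            {"min_length": 10, "max_length": 5},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AssemblyParams(**kwargs)
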