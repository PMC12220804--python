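import numpy as np
import pytest

from plvscan.seq_io import Contig, Interval, revcomp
from plvscan.tir_finder import (
    IRScoring,
    TIRPair,
    filter_candidates,
    find_inverted_repeats,
    recompute_pair,
    tir_identity,
)

from .conftest import random_dna
from .oracles import ir_oracle


def _mutate(rng, seq, n_sub):
    out = list(seq)
    for p in rng.choice(len(seq), size=n_sub, replace=False):
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def _planted_case(rng, arm_len, spacer_len, n_sub=0, lead=150, tail=150):
    arm = random_dna(rng, arm_len)
    arm3 = _mutate(rng, revcomp(arm), n_sub)
    seq = (
        random_dna(rng, lead)
        + arm
        + random_dna(rng, spacer_len)
        + arm3
        + random_dna(rng, tail)
    )
    return Contig("t", seq), lead, arm_len, spacer_len


class TestFindExact:
    def test_perfect_arms_score_and_identity(self):
        rng = np.random.default_rng(0)
        contig, lead, arm, spacer = _planted_case(rng, 200, 1000)
        (pair,) = find_inverted_repeats(contig)
        assert pair.score >= 600  # 200 matches, possibly chance-extended
        assert pair.arm_identity_pct == 100.0
        assert abs(pair.arm5.start - lead) <= 3
        assert abs(pair.arm3.end - (lead + 2 * arm + spacer)) <= 3

    def test_poly_a_contig_has_no_pairs(self):
        assert find_inverted_repeats(Contig("a", "A" * 500)) == []

    def test_score_recomputable_from_arms(self):
        rng = np.random.default_rng(1)
        contig, *_ = _planted_case(rng, 120, 400, n_sub=5)
        scoring = IRScoring()
        for pair in find_inverted_repeats(contig, scoring):
            assert recompute_pair(pair, contig, scoring).score == pair.score


class TestOracleEquivalence:
    @pytest.mark.parametrize("case", range(40))
    def test_small_inputs_match_exhaustive_dp(self, case):
        rng = np.random.default_rng(1000 + case)
        kind = case % 4
        if kind == 0:  # pure random, usually empty output
            seq = random_dna(rng, int(rng.integers(60, 300)))
        elif kind == 1:  # one planted IR
            arm = int(rng.integers(18, 45))
            c, *_ = _planted_case(
                rng, arm, int(rng.integers(20, 120)), n_sub=int(rng.integers(0, 3)),
                lead=int(rng.integers(5, 40)), tail=int(rng.integers(5, 40)))
            seq = c.seq[:300]
        elif kind == 2:  # two planted IRs
            a1, a2 = int(rng.integers(18, 30)), int(rng.integers(18, 30))
            s = (random_dna(rng, 10) + (p1 := random_dna(rng, a1))
                 + random_dna(rng, 30) + revcomp(p1) + random_dna(rng, 20)
                 + (p2 := random_dna(rng, a2)) + random_dna(rng, 40)
                 + revcomp(p2) + random_dna(rng, 10))
            seq = s[:300]
        else:  # N-containing
            seq = "".join(
                rng.choice(list("ACGTN"), size=int(rng.integers(60, 200)),
                           p=[0.23, 0.23, 0.23, 0.23, 0.08]))
        contig = Contig("x", seq)
        got = [
            (p.arm5.start, p.arm5.end, p.arm3.start, p.arm3.end, p.score)
            for p in find_inverted_repeats(contig)
        ]
        assert got == ir_oracle(seq)


class TestStrandSymmetry:
    def test_mirrored_coordinates_on_revcomp(self):
        rng = np.random.default_rng(2)
        contig, *_ = _planted_case(rng, 150, 800)
        fwd = find_inverted_repeats(contig)
        rev = find_inverted_repeats(Contig("r", revcomp(contig.seq)))
        n = contig.length
        mirrored = sorted(
            (n - p.arm3.end, n - p.arm3.start, n - p.arm5.end, n - p.arm5.start, p.score)
            for p in rev
        )
        got = sorted(
            (p.arm5.start, p.arm5.end, p.arm3.start, p.arm3.end, p.score)
            for p in fwd
        )
        assert got == mirrored


class TestSeededPath:
    def test_planted_pairs_recovered_on_long_contig(self):
        rng = np.random.default_rng(3)
        pieces = []
        expected = []
        pos = 0
        for arm_len, spacer in [(200, 8000), (500, 12_000), (120, 7_000)]:
            lead = random_dna(rng, 5_000)
            arm = random_dna(rng, arm_len)
            pieces += [lead, arm, random_dna(rng, spacer), revcomp(arm)]
            start = pos + len(lead)
            end = start + 2 * arm_len + spacer
            expected.append((start, end))
            pos = end + 5_000 - (5_000 - len(lead)) + 0  # recompute below
            pos = sum(len(x) for x in pieces)
        pieces.append(random_dna(rng, 5_000))
        contig = Contig("long", "".join(pieces))
        pairs = find_inverted_repeats(contig)
        for start, end in expected:
            assert any(
                abs(p.insert.start - start) <= 5 and abs(p.insert.end - end) <= 5
                for p in pairs
            ), (start, end)

    def test_nested_pairs_both_reported(self):
        rng = np.random.default_rng(4)
        inner_arm = random_dna(rng, 150)
        inner = inner_arm + random_dna(rng, 4_000) + revcomp(inner_arm)
        outer_arm = random_dna(rng, 200)
        seq = (
            random_dna(rng, 3_000)
            + outer_arm
            + random_dna(rng, 3_000)
            + inner
            + random_dna(rng, 3_000)
            + revcomp(outer_arm)
            + random_dna(rng, 3_000)
        )
        pairs = find_inverted_repeats(Contig("nest", seq))
        spans = sorted(p.insert.length for p in pairs)
        assert len(pairs) == 2
        assert spans[0] < spans[1]


class TestFilterCandidates:
    def _pair(self, insert_len, arm_len):
        arm5 = Interval("c", 0, arm_len)
        arm3 = Interval("c", insert_len - arm_len, insert_len)
        return TIRPair(
            contig_id="c", arm5=arm5, arm3=arm3,
            insert=Interval("c", 0, insert_len),
            score=100, arm_identity_pct=100.0, n_mismatches=0, n_gaps=0,
        )

    def test_stated_bounds_inclusive(self):
        assert filter_candidates([self._pair(5_999, 100)]) == []
        kept = filter_candidates([self._pair(6_000, 100)])
        assert len(kept) == 1
        assert filter_candidates([self._pair(80_001, 100)]) == []
        assert len(filter_candidates([self._pair(80_000, 8_000)])) == 1
        assert filter_candidates([self._pair(20_000, 99)]) == []
        assert filter_candidates([self._pair(20_000, 8_001)]) == []

    def test_hand_counted_mixed_list(self):
        cases = [  # (insert, arm, should_pass)
            (5_000, 200, False), (6_000, 100, True), (10_000, 50, False),
            (12_000, 4_000, True), (80_000, 8_000, True),
            (81_000, 500, False), (20_000, 8_001, False), (6_001, 101, True),
            (79_999, 7_999, True), (5_999, 99, False),
        ]
        pairs = [self._pair(i, a) for i, a, _ in cases]
        kept = filter_candidates(pairs)
        assert len(kept) == sum(ok for *_, ok in cases)

    def test_idempotent_and_order_preserving(self):
        pairs = [self._pair(6_000 + 1000 * i, 150) for i in range(5)]
        once = filter_candidates(pairs)
        assert filter_candidates(once) == once
        starts = [p.insert.length for p in once]
        assert starts == sorted(starts)


class TestIdentity:
    def test_identical_arms_are_100(self):
        rng = np.random.default_rng(5)
        arm = random_dna(rng, 100)
        contig = Contig(
            "i",
            random_dna(rng, 50) + arm + random_dna(rng, 500) + revcomp(arm) + random_dna(rng, 50),
        )
        pair = TIRPair(
            contig_id="i",
            arm5=Interval("i", 50, 150),
            arm3=Interval("i", 650, 750),
            insert=Interval("i", 50, 750),
            score=300, arm_identity_pct=100.0, n_mismatches=0, n_gaps=0,
        )
        assert tir_identity(pair, contig) == 100.0

    def test_three_substitutions_in_100bp(self):
        rng = np.random.default_rng(6)
        arm = random_dna(rng, 100)
        arm3 = _mutate(rng, revcomp(arm), 3)
        contig = Contig(
            "i", random_dna(rng, 50) + arm + random_dna(rng, 500) + arm3 + random_dna(rng, 50)
        )
        pair = TIRPair(
            contig_id="i",
            arm5=Interval("i", 50, 150),
            arm3=Interval("i", 650, 750),
            insert=Interval("i", 50, 750),
            score=0, arm_identity_pct=0.0, n_mismatches=0, n_gaps=0,
        )
        assert tir_identity(pair, contig) == pytest.approx(97.0)

    def test_unrelated_arms_score_low(self):
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 1_000)
        pair = TIRPair(
            contig_id="u",
            arm5=Interval("u", 0, 100),
            arm3=Interval("u", 900, 1_000),
            insert=Interval("u", 0, 1_000),
            score=0, arm_identity_pct=0.0, n_mismatches=0, n_gaps=0,
        )
        assert tir_identity(pair, Contig("u", seq)) < 60
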