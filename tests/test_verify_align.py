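import numpy as np
import pytest

import _oracles
from chromalign import Genome, GenomeSequence
from chromalign.candidate_engine import Candidate
from chromalign.verify_align import (
    AlignmentResult,
    VerifyParams,
    banded_edit_distance,
    compute_mapq,
    split_map,
    traceback_positions,
    verify_candidates,
)
from conftest import random_seq


def plant_errors(rng, seq, n_sub, n_indel=0):
    s = list(seq)
    for _ in range(n_sub):
        i = int(rng.integers(0, len(s)))
        s[i] = "ACGT"[(("ACGT".index(s[i]) if s[i] in "ACGT" else 0) + 1) % 4]
    for _ in range(n_indel):
        i = int(rng.integers(1, len(s)))
        if rng.random() < 0.5:
            del s[i]
        else:
            s.insert(i, "ACGT"[rng.integers(0, 4)])
    return "".join(s)


class TestBandedEditDistance:
    def test_identity(self):
        assert banded_edit_distance("ACGT", "ACGT", 8) == (0, 4)

    def test_single_substitution(self):
        assert banded_edit_distance("ACGT", "ACCT", 8) == (1, 4)

    def test_reject_over_threshold(self):
        assert banded_edit_distance("AAAAAAAA", "TTTTTTTT", 3) is None

    @pytest.mark.parametrize("read_len", [20, 40, 63])
    def test_matches_infix_dp_oracle(self, read_len):
        rng = np.random.default_rng(read_len)
        t = 8
        for _ in range(20):
            window = random_seq(rng, read_len + 2 * t)
            start = int(rng.integers(0, 2 * t))
            read = plant_errors(
                rng, window[start : start + read_len],
                n_sub=int(rng.integers(0, 6)), n_indel=int(rng.integers(0, 3)),
            )[:read_len]
            if len(read) < 15:
                continue
            oracle, _spans = _oracles.infix_dp(read, window)
            got = banded_edit_distance(read, window, t)
            if oracle <= t:
                assert got is not None and got[0] == oracle
            else:
                assert got is None

    @pytest.mark.parametrize("read_len", [64, 65, 100, 150, 300])
    def test_matches_edlib_oracle_beyond_one_word(self, read_len):
        # multi-word bit vectors at >64 bp must agree with an independent
        # infix-alignment implementation
        import edlib

        rng = np.random.default_rng(read_len)
        t = 8
        for _ in range(40):
            window = random_seq(rng, read_len + 2 * t)
            start = int(rng.integers(0, 2 * t))
            read = plant_errors(
                rng, window[start : start + read_len],
                n_sub=int(rng.integers(0, 6)), n_indel=int(rng.integers(0, 3)),
            )[:read_len]
            oracle = edlib.align(read, window, mode="HW")["editDistance"]
            got = banded_edit_distance(read, window, t)
            if oracle <= t:
                assert got is not None and got[0] == oracle
            else:
                assert got is None


class TestTraceback:
    def test_exact_match_offsets(self):
        window = "TTT" + "ACGTACGT" + "GG"
        dist, end = banded_edit_distance("ACGTACGT", window, 4)
        start, end2 = traceback_positions("ACGTACGT", window, dist, end)
        assert (start, end2) == (3, 11)

    def test_deletion_lengthens_reference_span(self):
        ref = "TTGCAGGTACCTGAC"
        read = ref[2:6] + ref[7:13]  # reference base 6 deleted from the read
        dist, end = banded_edit_distance(read, ref, 4)
        start, end2 = traceback_positions(read, ref, dist, end)
        assert dist == 1
        assert (end2 - start) == len(read) + 1

    def test_start_is_an_argmin_of_prefix_anchored_distance(self):
        rng = np.random.default_rng(77)
        for _ in range(40):
            window = random_seq(rng, 60)
            read = plant_errors(rng, window[10:40], n_sub=2, n_indel=1)
            res = banded_edit_distance(read, window, 8)
            if res is None:
                continue
            dist, end = res
            start, end2 = traceback_positions(read, window, dist, end)
            oracle_dist, spans = _oracles.infix_dp(read, window)
            assert dist == oracle_dist
            assert (start, end2) in spans


def _genome_with(seq: str, name="chr1") -> Genome:
    return Genome([GenomeSequence(name, seq)])


class TestVerifyCandidates:
    def test_planted_read_beats_decoys(self):
        rng = np.random.default_rng(4)
        g = _genome_with(random_seq(rng, 3000))
        read = plant_errors(rng, g.concat[1000:1100], n_sub=2)
        cands = [Candidate(1000, "+"), Candidate(2000, "+"), Candidate(300, "+")]
        out = verify_candidates(read, cands, g, VerifyParams())
        assert out.best is not None
        assert out.best.edit_distance == 2
        assert abs(out.best.start - 1000) <= 2
        assert out.num_best == 1

    def test_two_copy_repeat_ties(self):
        rng = np.random.default_rng(5)
        unit = random_seq(rng, 200)
        g = _genome_with(random_seq(rng, 500) + unit + random_seq(rng, 500) + unit)
        read = unit[50:150]
        cands = [Candidate(550, "+"), Candidate(1250, "+")]
        out = verify_candidates(read, cands, g, VerifyParams())
        assert out.num_best == 2
        assert out.best.start == 550  # smallest coordinate wins the report
        assert compute_mapq(out.best, out.second_best_distance, out.num_best) == 0

    def test_empty_candidates_unmapped(self):
        g = _genome_with("ACGT" * 100)
        out = verify_candidates("ACGTACGT", [], g, VerifyParams())
        assert out.best is None and out.num_best == 0

    def test_all_rejected_unmapped(self):
        rng = np.random.default_rng(6)
        g = _genome_with(random_seq(rng, 1000))
        read = "ACGT" * 25
        out = verify_candidates(read, [Candidate(500, "+")], g, VerifyParams(error_threshold=2))
        if out.best is not None:  # random window could fit by chance; distance must obey budget
            assert out.best.edit_distance <= 2

    def test_batching_does_not_change_results(self):
        rng = np.random.default_rng(7)
        g = _genome_with(random_seq(rng, 5000))
        read = plant_errors(rng, g.concat[2000:2100], n_sub=3)
        cands = [Candidate(p, s) for p in (100, 900, 2000, 2004, 3500) for s in "+-"]
        base = verify_candidates(read, cands, g, VerifyParams())
        for bs in (1, 2, 3, 100):
            out = verify_candidates(read, cands, g, VerifyParams(), batch_size=bs)
            assert (out.best, out.second_best_distance, out.num_best) == (
                base.best, base.second_best_distance, base.num_best
            )

    def test_strand_consistency(self):
        from chromalign.io_formats import revcomp

        rng = np.random.default_rng(8)
        g = _genome_with(random_seq(rng, 2000))
        for _ in range(30):
            p = int(rng.integers(0, 1900))
            read = plant_errors(rng, g.concat[p : p + 80], n_sub=1)
            fwd = verify_candidates(read, [Candidate(p, "+")], g, VerifyParams())
            rev = verify_candidates(revcomp(read), [Candidate(p, "-")], g, VerifyParams())
            assert fwd.best is not None and rev.best is not None
            assert (fwd.best.start, fwd.best.end) == (rev.best.start, rev.best.end)
            assert fwd.best.strand == "+" and rev.best.strand == "-"


class TestComputeMapq:
    def _res(self, dist):
        return AlignmentResult(Candidate(0, "+"), 0, 100, "+", dist)

    def test_ambiguity_floors_at_zero(self):
        assert compute_mapq(self._res(1), 1, num_best=2) == 0

    def test_sole_candidate_max(self):
        assert compute_mapq(self._res(3), None, num_best=1) == 60

    def test_margin_scaling(self):
        assert compute_mapq(self._res(2), 3, num_best=1) == 20

    def test_monotone_in_second_best(self):
        prev = -1
        for second in range(2, 10):
            q = compute_mapq(self._res(2), second, num_best=1)
            assert q >= prev
            prev = q


class TestSplitMap:
    def _chimera_genome(self, rng):
        a = random_seq(rng, 2000)
        return _genome_with(a)

    def test_chimeric_prefix_maps_with_score(self):
        rng = np.random.default_rng(10)
        g = self._chimera_genome(rng)
        # 60 bp from the candidate locus + 40 bp of unalignable sequence
        read = g.concat[500:560] + "N" * 40
        res = split_map(read, [Candidate(500, "+")], g, VerifyParams())
        assert res is not None and res.is_split
        # each N row adds exactly one edit, so score stays mapped-len - dist
        assert res.score == 60
        assert res.start == 500

    def test_score_is_mapped_length_minus_edits(self):
        rng = np.random.default_rng(11)
        g = self._chimera_genome(rng)
        core = plant_errors(rng, g.concat[300:380], n_sub=3)  # 80 bp, 3 edits
        read = core + "N" * 20
        res = split_map(read, [Candidate(300, "+")], g, VerifyParams())
        assert res is not None
        assert res.score == 80 - 3

    def test_second_round_with_backward_extension(self):
        rng = np.random.default_rng(12)
        g = self._chimera_genome(rng)
        # first 15 bases unalignable, remainder exact at 800
        tail = g.concat[815:900]  # read positions 15..99 match the reference
        read = "N" * 15 + tail
        res = split_map(read, [Candidate(800, "+")], g, VerifyParams())
        assert res is not None and res.is_split
        # round two maps read[20:], backward exact extension recovers 15..19
        assert res.clip5 == 15
        assert res.start == 815

    def test_second_round_extension_stops_at_mismatch(self):
        rng = np.random.default_rng(13)
        g = self._chimera_genome(rng)
        tail = list(g.concat[815:900])
        read = "N" * 15 + "".join(tail)
        # corrupt read base 17 so the backward extension cannot pass it
        bad = "ACGT"[("ACGT".index(read[17]) + 1) % 4]
        read = read[:17] + bad + read[18:]
        res = split_map(read, [Candidate(800, "+")], g, VerifyParams())
        assert res is not None
        assert res.clip5 == 18
        assert res.start == 818

    def test_minus_strand_split(self):
        from chromalign.io_formats import revcomp

        rng = np.random.default_rng(14)
        g = self._chimera_genome(rng)
        read = revcomp(g.concat[500:560]) + "N" * 40
        res = split_map(read, [Candidate(500, "-")], g, VerifyParams())
        assert res is not None and res.strand == "-"
        assert res.end == 560
        assert res.score == 60

    def test_both_rounds_fail_unmapped(self):
        rng = np.random.default_rng(15)
        g = self._chimera_genome(rng)
        res = split_map("N" * 100, [Candidate(500, "+")], g, VerifyParams())
        assert res is None

    def test_prefix_length_matches_oracle(self):
        rng = np.random.default_rng(16)
        g = self._chimera_genome(rng)
        t = 8
        for _ in range(10):
            p = int(rng.integers(0, 1500))
            keep = int(rng.integers(35, 70))
            read = plant_errors(rng, g.concat[p : p + keep], n_sub=1) + "N" * (100 - keep)
            res = split_map(read, [Candidate(p, "+")], g, VerifyParams())
            window = g.concat[max(0, p - t) : p + 100 + t]
            oracle = _oracles.prefix_anchored_best(read, window, t)
            assert res is not None and oracle is not None
            assert res.score == oracle[0] - oracle[1]
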