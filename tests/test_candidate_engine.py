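import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from chromalign.candidate_engine import (
    CACHE_SIZE,
    COUNT_ARRAY_SIZE,
    Candidate,
    CandidateCache,
    CandidateParams,
    MinimizerVector,
    best_candidate,
    cache_hash_f,
    cache_hash_h,
    generate_candidates,
    pair_filter,
    supplement_candidates,
)
from chromalign.minimizer_index import (
    Anchors,
    MinimizerIndex,
    MinimizerParams,
    Minimizers,
)


def plus_anchors(pairs):
    return Anchors.from_lists([(x, y, 0) for x, y in pairs])


class TestGenerateCandidates:
    def test_merge_with_min_support(self):
        anchors = plus_anchors([(1000, 10), (1050, 60), (2000, 5)])
        cands = generate_candidates(anchors, 100, 17, CandidateParams(error_threshold=0, min_support=2))
        assert cands == [Candidate(990, "+", 2)]

    def test_min_support_one_keeps_singletons(self):
        anchors = plus_anchors([(1000, 10), (1050, 60), (2000, 5)])
        cands = generate_candidates(anchors, 100, 17, CandidateParams(error_threshold=0, min_support=1))
        assert cands == [Candidate(990, "+", 2), Candidate(1995, "+", 1)]

    def test_empty_anchor_list(self):
        assert generate_candidates(Anchors.empty(), 100, 17, CandidateParams()) == []

    def test_reverse_strand_uses_mirrored_formula(self):
        # minus-strand anchor: position = x - (L - k - y)
        anchors = Anchors.from_lists([(5000, 10, 1)])
        (cand,) = generate_candidates(anchors, 100, 17, CandidateParams())
        assert cand == Candidate(5000 - (100 - 17 - 10), "-", 1)

    @pytest.mark.parametrize("threshold,min_support", [(0, 1), (8, 1), (8, 2), (3, 3)])
    def test_matches_bruteforce_grouping(self, threshold, min_support):
        rng = np.random.default_rng(threshold * 10 + min_support)
        params = CandidateParams(error_threshold=threshold, min_support=min_support)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            xs = rng.integers(0, 500, size=n)
            ys = np.zeros(n, dtype=np.int64)
            cands = generate_candidates(
                Anchors(xs.astype(np.int64), ys, np.zeros(n, dtype=np.uint8)), 100, 17, params
            )
            expected = _oracles.brute_merge_candidates(xs.tolist(), threshold, min_support)
            assert [(c.position, c.multiplicity) for c in cands] == expected

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        positions=st.lists(st.integers(0, 1000), min_size=1, max_size=40),
        threshold=st.integers(0, 12),
        min_support=st.integers(1, 4),
    )
    def test_merge_property_matches_oracle(self, positions, threshold, min_support):
        xs = np.array(positions, dtype=np.int64)
        cands = generate_candidates(
            Anchors(xs, np.zeros(len(xs), dtype=np.int64), np.zeros(len(xs), dtype=np.uint8)),
            100, 17, CandidateParams(error_threshold=threshold, min_support=min_support),
        )
        expected = _oracles.brute_merge_candidates(positions, threshold, min_support)
        assert [(c.position, c.multiplicity) for c in cands] == expected

    def test_order_independence(self):
        rng = np.random.default_rng(9)
        xs = rng.integers(0, 300, size=30).astype(np.int64)
        ys = rng.integers(0, 50, size=30).astype(np.int64)
        ss = rng.integers(0, 2, size=30).astype(np.uint8)
        params = CandidateParams(error_threshold=5)
        base = generate_candidates(Anchors(xs, ys, ss), 100, 17, params)
        perm = rng.permutation(30)
        shuffled = generate_candidates(Anchors(xs[perm], ys[perm], ss[perm]), 100, 17, params)
        assert sorted(base, key=str) == sorted(shuffled, key=str)


class TestPairFilter:
    def test_proper_pair_kept(self):
        pairs = pair_filter([Candidate(1000, "+")], [Candidate(1200, "-")], 100, 100, 30, 2000)
        assert len(pairs) == 1  # fragment length 300

    def test_fragment_too_long_dropped(self):
        assert pair_filter([Candidate(1000, "+")], [Candidate(5900, "-")], 100, 100, 30, 2000) == []

    def test_same_strand_dropped(self):
        assert pair_filter([Candidate(1000, "+")], [Candidate(1200, "+")], 100, 100, 30, 2000) == []

    def test_reverse_orientation_symmetric(self):
        pairs = pair_filter([Candidate(1200, "-")], [Candidate(1000, "+")], 100, 100, 30, 2000)
        assert len(pairs) == 1


def vec(keys, offsets=(), first=5, tail=3, read_len=100):
    return MinimizerVector(tuple(keys), tuple(offsets), first, tail, read_len)


class TestCacheHashes:
    def test_h_printed_formula(self):
        assert cache_hash_h(vec([100, 50, 200], (10, 10))) == 300

    def test_h_strand_agnostic(self):
        assert cache_hash_h(vec([200, 50, 100], (10, 10))) == 300

    def test_h_modular_wraparound(self):
        v = vec([2_000_000, 2_000_000], (5,))
        assert cache_hash_h(v) == 4_000_000 % 2_000_003 == 1_999_997

    def test_f_xor_formula(self):
        assert cache_hash_f(vec([100, 200], (4,))) == (100 ^ 200) % 103 == 69

    def test_f_equal_ends_is_zero(self):
        assert cache_hash_f(vec([77, 77], (4,))) == 0

    def test_f_strand_agnostic(self):
        assert cache_hash_f(vec([100, 200], (4,))) == cache_hash_f(vec([200, 100], (4,)))

    def test_single_minimizer_vector(self):
        v = vec([12345])
        assert cache_hash_h(v) == (2 * 12345) % CACHE_SIZE
        assert cache_hash_f(v) == 0

    def test_stated_table_sizes_are_defaults(self):
        cache = CandidateCache()
        assert cache.size == CACHE_SIZE == 2_000_003
        assert cache.count_array_size == COUNT_ARRAY_SIZE == 103


class TestCacheLookup:
    def test_empty_cache_misses(self):
        cache = CandidateCache()
        assert cache.lookup(vec([1, 2], (7,))) is None
        assert cache.misses == 1

    def test_identical_vector_hits_with_same_candidates(self):
        cache = CandidateCache()
        v = vec([1, 2], (7,))
        cands = [Candidate(500, "+", 3), Candidate(900, "-", 1)]
        cache.lookup(v)
        cache.update(v, cands)
        assert cache.lookup(v) == cands
        assert cache.hits == 1

    def test_shifted_read_rebased(self):
        cache = CandidateCache()
        v1 = vec([1, 2], (7,), first=10, tail=3)
        cache.update(v1, [Candidate(500, "+", 2), Candidate(800, "-", 1)])
        # same vector seen in a read whose first minimizer sits 4 bases later
        v2 = vec([1, 2], (7,), first=14, tail=7)
        got = cache.lookup(v2)
        assert got == [Candidate(496, "+", 2), Candidate(796, "-", 1)]

    def test_reverse_complement_read_hits_with_flipped_strands(self):
        cache = CandidateCache()
        v = vec([1, 2], (7,), first=10, tail=3)
        cache.update(v, [Candidate(500, "+", 2)])
        # the rc read's vector is reversed; offsets swap roles
        vr = vec([2, 1], (7,), first=3, tail=10)
        got = cache.lookup(vr)
        assert got == [Candidate(500, "-", 2)]

    def test_fingerprint_collision_is_a_miss(self):
        cache = CandidateCache()
        v1 = vec([1, 2], (7,))
        cache.update(v1, [Candidate(500, "+", 1)])
        v2 = vec([1, 2], (9,))  # same h but different offsets
        assert cache_hash_h(v1) == cache_hash_h(v2)
        assert cache.lookup(v2) is None


class TestCacheUpdateRule:
    def test_first_update_admits(self):
        cache = CandidateCache()
        assert cache.update(vec([1, 2], (7,)), [Candidate(5, "+", 1)]) is True

    def _fill_entry(self, cache, h_sum, n_other, start_key=1000):
        """n_other updates to the same entry from distinct other-cell vectors."""
        made = 0
        key = start_key
        target = cache_hash_f(vec([3, h_sum - 3], (1,)))
        while made < n_other:
            a = key
            b = h_sum + cache.size - a  # a + b = h_sum (mod table size)
            key += 1
            if b <= 0:
                raise RuntimeError("ran out of keys")
            v = vec([a, b], (1,))
            if cache_hash_f(v) == target:
                continue  # keep the probe cell clean
            cache.update(v, [])
            made += 1

    def test_count_over_20_percent_with_majority_replaces(self):
        cache = CandidateCache(size=10_007, count_array_size=103)
        probe = vec([3, 101], (1,))
        self._fill_entry(cache, 104, 75)
        replaced = False
        for _ in range(25):
            replaced = cache.update(probe, [Candidate(42, "+", 1)])
        # 25th update: cell count 25 of total 100, majority -> admitted
        assert replaced is True
        assert cache.lookup(probe) == [Candidate(42, "+", 1)]

    def test_count_at_or_below_20_percent_rejected(self):
        cache = CandidateCache(size=10_007, count_array_size=103)
        probe = vec([3, 101], (1,))
        self._fill_entry(cache, 104, 85)
        results = [cache.update(probe, [Candidate(42, "+", 1)]) for _ in range(15)]
        # 15 of 100 is not more than 20%
        assert not any(results)
        assert cache.lookup(probe) is None

    def test_non_majority_occupant_rejected(self):
        cache = CandidateCache(size=10_007, count_array_size=103)
        # two vectors in the SAME count cell: same m1^mM, different offsets
        v_major = vec([3, 101], (1,))
        v_minor = vec([3, 101], (2,))
        for _ in range(20):
            cache.update(v_major, [Candidate(1, "+", 1)])
        results = [cache.update(v_minor, [Candidate(2, "+", 1)]) for _ in range(5)]
        # cell count 25/25 passes the 20% bar, but v_minor never becomes
        # the cell's dominant occupant
        assert not any(results)
        got = cache.lookup(v_major)
        assert got == [Candidate(1, "+", 1)]


def _toy_index_single_key(key, positions, max_occ=1):
    keys = np.array([key], dtype=np.uint64)
    starts = np.array([0, len(positions)], dtype=np.int64)
    pos = np.array(positions, dtype=np.int64)
    strands = np.zeros(len(positions), dtype=np.uint8)
    params = MinimizerParams(max_occ=max_occ)
    return MinimizerIndex(params, keys, starts, pos, strands, [("c", 10 ** 9)], "x")


class TestSupplement:
    def test_masked_minimizer_rescued_within_window(self):
        # occurrence list {500, 9800, 50000}; mate at 10000, range max 1000
        idx = _toy_index_single_key(7, [500, 9_800, 50_000], max_occ=1)
        mins = Minimizers(
            np.array([0], dtype=np.int64), np.array([7], dtype=np.uint64),
            np.zeros(1, dtype=np.uint8),
        )
        params = CandidateParams(fragment_min=0, fragment_max=1000)
        cands = supplement_candidates(idx, mins, 100, Candidate(10_000, "-", 5), params)
        assert cands == [Candidate(9_800, "+", 1)]

    def test_no_mate_candidate_is_noop(self):
        idx = _toy_index_single_key(7, [500])
        mins = Minimizers(
            np.array([0], dtype=np.int64), np.array([7], dtype=np.uint64),
            np.zeros(1, dtype=np.uint8),
        )
        assert supplement_candidates(idx, mins, 100, None, CandidateParams()) == []

    def test_never_outside_mate_window(self):
        rng = np.random.default_rng(2)
        occ = np.sort(rng.integers(0, 10 ** 6, size=200)).tolist()
        idx = _toy_index_single_key(7, occ, max_occ=1)
        mins = Minimizers(
            np.array([40], dtype=np.int64), np.array([7], dtype=np.uint64),
            np.ones(1, dtype=np.uint8),
        )
        params = CandidateParams(fragment_min=30, fragment_max=2000)
        mate = Candidate(500_000, "+", 2)
        for c in supplement_candidates(idx, mins, 100, mate, params):
            assert 498_000 <= c.position <= 502_000

    def test_best_candidate_prefers_multiplicity(self):
        cands = [Candidate(10, "+", 1), Candidate(99, "-", 4), Candidate(5, "+", 4)]
        assert best_candidate(cands) == Candidate(5, "+", 4)
        assert best_candidate([]) is None
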