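"""Sorting-based candidate generation, the frequent-read cache, mate rescue.

A candidate is a putative mapping start position on the reference,
estimated from an anchor (x, y) as x - y on the forward strand; on the
reverse strand the mirrored formula x - (L - k - y) is used so that a
candidate is always the leftmost reference base of the read. Raw candidate
positions from all anchors are sorted and merged in a linear scan: adjacent
positions within the error threshold collapse into one candidate whose
position is the smallest member and whose multiplicity is the number of
supporting anchors.

The candidate cache avoids repeating this work for frequent reads (reads
from peak regions). It is a fixed-size hash table keyed by the read's
minimizer vector (the M minimizer keys plus the M-1 offsets between them);
the entry index is h(m) = (m1 + mM) mod N, which is identical for a read
and its reverse complement. Each entry keeps a small count array of size N'
addressed by f(m) = (m1 XOR mM) mod N' and, per cell, a Boyer-Moore
majority tracker; the stored candidates are replaced only when the vector's
cell count exceeds 20% of the entry total AND the vector is the cell's
dominant occupant. Cached candidates are stored with the contributing
read's frame offsets and re-based onto the querying read, so the cache is a
pure accelerator: final mappings are identical with and without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .minimizer_index import Anchors, MinimizerIndex, Minimizers

CACHE_SIZE = 2_000_003
COUNT_ARRAY_SIZE = 103


@dataclass(slots=True, frozen=True)
class Candidate:
    """A putative mapping start (leftmost reference base of the read)."""

    position: int
    strand: str  # '+' or '-'
    multiplicity: int = 1


@dataclass(slots=True)
class CandidateParams:
    error_threshold: int = 8  # edit budget; also the candidate merge radius
    min_support: int = 1  # minimum anchor multiplicity to keep a candidate
    fragment_min: int = 30
    fragment_max: int = 2000

    def __post_init__(self) -> None:
        if self.error_threshold < 0:
            raise ValueError("error_threshold must be >= 0")
        if self.fragment_min > self.fragment_max:
            raise ValueError("fragment range inverted")


def raw_candidate_positions(anchors: Anchors, read_len: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor estimated start positions, split by strand.

    Returns (plus_positions, minus_positions), unsorted.
    """
    minus = anchors.strand.astype(bool)
    plus_pos = anchors.x[~minus] - anchors.y[~minus]
    minus_pos = anchors.x[minus] - (read_len - k - anchors.y[minus])
    return plus_pos, minus_pos


def _merge_positions(
    positions: np.ndarray, threshold: int, min_support: int
) -> list[tuple[int, int]]:
    """Sort raw positions and merge runs of neighbors within ``threshold``.

    Returns (position, multiplicity) with position = smallest run member.
    """
    if len(positions) == 0:
        return []
    pos = np.sort(positions)
    breaks = np.flatnonzero(np.diff(pos) > threshold) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(pos)]])
    out = []
    for a, b in zip(starts, ends):
        mult = int(b - a)
        if mult >= min_support:
            out.append((int(pos[a]), mult))
    return out


def generate_candidates(
    anchors: Anchors, read_len: int, k: int, params: CandidateParams
) -> list[Candidate]:
    """Merged, multiplicity-weighted candidates from a read's anchors.

    Order-independent: shuffling anchors cannot change the result because
    positions are sorted before the merge scan.
    """
    plus_pos, minus_pos = raw_candidate_positions(anchors, read_len, k)
    cands = [
        Candidate(p, "+", m)
        for p, m in _merge_positions(plus_pos, params.error_threshold, params.min_support)
    ]
    cands += [
        Candidate(p, "-", m)
        for p, m in _merge_positions(minus_pos, params.error_threshold, params.min_support)
    ]
    return cands


def pair_filter(
    cands_r1: Sequence[Candidate],
    cands_r2: Sequence[Candidate],
    len_r1: int,
    len_r2: int,
    fragment_min: int,
    fragment_max: int,
) -> list[tuple[Candidate, Candidate]]:
    """Keep candidate pairs in proper forward-reverse orientation whose
    implied fragment length lies within [fragment_min, fragment_max]."""
    out = []
    for c1 in cands_r1:
        for c2 in cands_r2:
            if c1.strand == c2.strand:
                continue
            if c1.strand == "+":
                frag = (c2.position + len_r2) - c1.position
            else:
                frag = (c1.position + len_r1) - c2.position
            if fragment_min <= frag <= fragment_max:
                out.append((c1, c2))
    return out


def best_candidate(cands: Sequence[Candidate]) -> Optional[Candidate]:
    """The candidate with the most supporting anchors (ties: smallest
    position, then '+' strand) — used to anchor mate rescue."""
    if not cands:
        return None
    return min(cands, key=lambda c: (-c.multiplicity, c.position, c.strand))


# ---------------------------------------------------------------------------
# Minimizer vector and cache
# ---------------------------------------------------------------------------


@dataclass(slots=True, frozen=True)
class MinimizerVector:
    """The cache key of a read: its minimizer keys in read order plus the
    gaps between adjacent minimizer positions.

    ``first_offset`` (position of the first minimizer on the read) and
    ``tail_offset`` (distance from the last minimizer's k-mer end to the
    read's 3' end) re-base cached candidates between reads that share the
    vector but start at different genomic offsets.
    """

    keys: tuple[int, ...]
    offsets: tuple[int, ...]
    first_offset: int
    tail_offset: int
    read_len: int

    @classmethod
    def from_minimizers(cls, mins: Minimizers, read_len: int, k: int) -> "MinimizerVector":
        if len(mins) == 0:
            raise ValueError("cannot build a vector from zero minimizers")
        pos = mins.pos
        keys = tuple(int(v) for v in mins.key)
        offsets = tuple(int(d) for d in np.diff(pos))
        return cls(keys, offsets, int(pos[0]), int(read_len - k - pos[-1]), read_len)

    @property
    def m1(self) -> int:
        return self.keys[0]

    @property
    def mM(self) -> int:
        return self.keys[-1]

    def fingerprint(self) -> tuple:
        """Strand-canonical fingerprint: min of the vector and its reversal,
        so a read and its reverse complement compare equal."""
        fwd = (self.keys, self.offsets)
        rev = (self.keys[::-1], self.offsets[::-1])
        return min(fwd, rev)

    def orientation(self) -> int:
        """0 if the vector is already in canonical order, 1 if reversed."""
        fwd = (self.keys, self.offsets)
        rev = (self.keys[::-1], self.offsets[::-1])
        return 0 if fwd <= rev else 1


def cache_hash_h(vector: MinimizerVector, n: int = CACHE_SIZE) -> int:
    """Entry index (m1 + mM) mod N; commutative, hence strand-agnostic."""
    return (vector.m1 + vector.mM) % n


def cache_hash_f(vector: MinimizerVector, n_prime: int = COUNT_ARRAY_SIZE) -> int:
    """Count-cell index (m1 XOR mM) mod N'; XOR commutes, hence
    strand-agnostic."""
    return (vector.m1 ^ vector.mM) % n_prime


class _CacheEntry:
    __slots__ = (
        "counts", "total", "majority",
        "fp", "ori", "first_offset", "tail_offset", "plus", "minus",
    )

    def __init__(self, n_prime: int):
        self.counts = np.zeros(n_prime, dtype=np.int64)
        self.total = 0
        # Boyer-Moore majority tracker per count cell: cell -> [fingerprint, votes]
        self.majority: dict[int, list] = {}
        self.fp = None
        self.ori = 0
        self.first_offset = 0
        self.tail_offset = 0
        self.plus: list[tuple[int, int]] = []
        self.minus: list[tuple[int, int]] = []


class CandidateCache:
    """Fixed-size candidate cache with count-min-style admission.

    Entries are materialized lazily (a dict keyed by the h(m) slot), which
    is equivalent to a dense table of N slots whose untouched entries are
    empty.
    """

    def __init__(self, size: int = CACHE_SIZE, count_array_size: int = COUNT_ARRAY_SIZE):
        self.size = size
        self.count_array_size = count_array_size
        self.table: dict[int, _CacheEntry] = {}
        self.hits = 0
        self.misses = 0
        self.updates = 0

    def lookup(self, vector: MinimizerVector) -> Optional[list[Candidate]]:
        """Return re-based candidates on a HIT, None on a MISS.

        A HIT requires the stored fingerprint to equal the full vector
        (keys + offsets, strand-canonical). Candidates are translated into
        the querying read's frame; if the query matches in the reverse
        orientation the strands flip and the frame offsets swap roles.
        """
        entry = self.table.get(cache_hash_h(vector, self.size))
        if entry is None or entry.fp != vector.fingerprint():
            self.misses += 1
            return None
        self.hits += 1
        rel = entry.ori ^ vector.orientation()
        out: list[Candidate] = []
        if rel == 0:
            dplus = entry.first_offset - vector.first_offset
            dminus = entry.tail_offset - vector.tail_offset
            out += [Candidate(p + dplus, "+", m) for p, m in entry.plus]
            out += [Candidate(p + dminus, "-", m) for p, m in entry.minus]
        else:
            dminus = entry.first_offset - vector.tail_offset
            dplus = entry.tail_offset - vector.first_offset
            out += [Candidate(p + dplus, "+", m) for p, m in entry.minus]
            out += [Candidate(p + dminus, "-", m) for p, m in entry.plus]
        return out

    def update(self, vector: MinimizerVector, candidates: Sequence[Candidate]) -> bool:
        """Record a MISS for ``vector`` and admit it if it qualifies.

        Increments the count cell f(m) and the entry total, advances the
        cell's majority tracker, and replaces the stored entry iff the cell
        count exceeds 20% of the entry total and the vector is the cell's
        majority occupant. Returns True if the entry was replaced.
        """
        h = cache_hash_h(vector, self.size)
        entry = self.table.get(h)
        if entry is None:
            entry = _CacheEntry(self.count_array_size)
            self.table[h] = entry
        cell = cache_hash_f(vector, self.count_array_size)
        entry.counts[cell] += 1
        entry.total += 1
        fp = vector.fingerprint()
        tracker = entry.majority.get(cell)
        if tracker is None or tracker[1] == 0:
            entry.majority[cell] = [fp, 1]
        elif tracker[0] == fp:
            tracker[1] += 1
        else:
            tracker[1] -= 1
        tracker = entry.majority[cell]
        is_majority = tracker[0] == fp and tracker[1] > 0
        if entry.counts[cell] * 5 > entry.total and is_majority:
            entry.fp = fp
            entry.ori = vector.orientation()
            entry.first_offset = vector.first_offset
            entry.tail_offset = vector.tail_offset
            entry.plus = [(c.position, c.multiplicity) for c in candidates if c.strand == "+"]
            entry.minus = [(c.position, c.multiplicity) for c in candidates if c.strand == "-"]
            self.updates += 1
            return True
        return False


# ---------------------------------------------------------------------------
# Candidate supplement (mate rescue)
# ---------------------------------------------------------------------------


def supplement_candidates(
    index: MinimizerIndex,
    read_minimizers: Minimizers,
    read_len: int,
    mate_best: Optional[Candidate],
    params: CandidateParams,
) -> list[Candidate]:
    """Rescue candidates for a read end using its mate's best candidate.

    For each read minimizer — ignoring the occurrence mask — the sorted
    occurrence list is binary-searched for occurrences within
    mate_position +/- fragment_max, and candidate generation is re-run on
    the restricted anchors. Candidates outside the window are dropped.
    """
    if mate_best is None or len(read_minimizers) == 0:
        return []
    k = index.params.k
    lo = mate_best.position - params.fragment_max
    hi = mate_best.position + params.fragment_max
    xs, ys, ss = [], [], []
    for p, key, rstrand in zip(read_minimizers.pos, read_minimizers.key, read_minimizers.strand):
        pos, ref_strand = index.occurrences(int(key))
        if len(pos) == 0:
            continue
        a = int(np.searchsorted(pos, lo, side="left"))
        b = int(np.searchsorted(pos, hi, side="right"))
        if b <= a:
            continue
        xs.append(pos[a:b])
        ys.append(np.full(b - a, p, dtype=np.int64))
        ss.append(ref_strand[a:b] ^ rstrand)
    if not xs:
        return []
    anchors = Anchors(np.concatenate(xs), np.concatenate(ys), np.concatenate(ss))
    cands = generate_candidates(anchors, read_len, k, params)
    return [c for c in cands if lo <= c.position <= hi]
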