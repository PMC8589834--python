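"""Candidate verification with a banded Myers bit-parallel edit distance.

Each candidate start position is verified by computing the minimum edit
distance between the full read and the reference window of width
read_len + 2*error_threshold centered on the candidate — the window width
itself restricts alignments to a diagonal band of half-width
error_threshold, and distances above the threshold are rejected. The
computation is Myers' bit-parallel approximate-matching recurrence: the
dynamic-programming column is encoded in bit vectors (held in Python
arbitrary-precision integers, so reads longer than a machine word are
handled by the same code path), the text is scanned left to right, and the
score at the bottom row gives the distance of the read against every
window end position with a free start.

The exact start coordinate is traced back by re-running the scan on the
reversed strings from the best end position. MAPQ is assigned by a
deterministic convention (ambiguity floors it at 0; margin between best
and runner-up distance scales it up to 60). Hi-C reads that fail the edit
threshold fall through to split mapping, which keeps the longest
prefix-anchored mapping, optionally retries after excluding the first
20 bases, and extends back by maximal exact matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .candidate_engine import Candidate
from .io_formats import Genome, revcomp

_BASE_ORD = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(slots=True)
class VerifyParams:
    error_threshold: int = 8  # band half-width and edit budget
    min_split_length: int = 30  # shortest split mapping worth keeping
    split_5prime_skip: int = 20  # bases excluded in the second split round

    def __post_init__(self) -> None:
        if self.min_split_length <= 0:
            raise ValueError("min_split_length must be positive")


@dataclass(slots=True)
class AlignmentResult:
    """A verified mapping in concatenated reference coordinates."""

    candidate: Candidate
    start: int
    end: int
    strand: str
    edit_distance: int
    score: int = 0  # split mode: mapped length - edit distance
    is_split: bool = False
    clip5: int = 0  # read bases excluded at the 5' end (split mode)


@dataclass(slots=True)
class VerifyOutcome:
    best: Optional[AlignmentResult]
    second_best_distance: Optional[int]
    num_best: int = 0


def build_peq(pattern: str) -> dict[str, int]:
    """Per-base match bitmasks; N (or any non-ACGT) matches nothing."""
    peq: dict[str, int] = {"A": 0, "C": 0, "G": 0, "T": 0}
    for i, ch in enumerate(pattern):
        if ch in peq:
            peq[ch] |= 1 << i
    return peq


def _myers_scan(peq: dict[str, int], m: int, text: str) -> tuple[int, int]:
    """Myers' approximate-matching scan of ``text``.

    Returns (min_distance, end_offset): the minimum edit distance of the
    full pattern against any text prefix-end with a free start, and the
    smallest number of text characters consumed that achieves it.
    """
    full = (1 << m) - 1
    top = 1 << (m - 1)
    pv = full
    mv = 0
    score = m
    best = m
    best_end = 0
    get = peq.get
    for j, c in enumerate(text):
        eq = get(c, 0)
        xv = eq | mv
        xh = ((((eq & pv) + pv) ^ pv) | eq) & full
        ph = mv | (~(xh | pv) & full)
        mh = pv & xh
        if ph & top:
            score += 1
        elif mh & top:
            score -= 1
        ph = (ph << 1) & full
        pv = mh << 1 | (~(xv | ph) & full)
        mv = ph & xv
        if score < best:
            best = score
            best_end = j + 1
    return best, best_end


def banded_edit_distance(
    read: str,
    ref_window: str,
    error_threshold: int,
    peq: Optional[dict[str, int]] = None,
) -> Optional[tuple[int, int]]:
    """Minimum edit distance of the full read inside a reference window.

    Returns (edit_distance, best_end_offset) or None (REJECT) when the
    minimum exceeds ``error_threshold``. ``peq`` may be precomputed once
    per read and shared across candidate windows.
    """
    m = len(read)
    if m == 0:
        raise ValueError("empty read")
    if peq is None:
        peq = build_peq(read)
    dist, end = _myers_scan(peq, m, ref_window)
    if dist > error_threshold:
        return None
    return dist, end


def traceback_positions(
    read: str, ref_window: str, edit_distance: int, best_end_offset: int
) -> tuple[int, int]:
    """Exact (start, end) window offsets of the best alignment.

    Derived by scanning the reversed strings: the distance of the read
    against window[s:end] equals the distance of the reversed read against
    the reversed prefix, so the reversed scan locates the span. Among
    equal-distance spans the shortest is chosen.
    """
    rpat = read[::-1]
    rtext = ref_window[:best_end_offset][::-1]
    dist, consumed = _myers_scan(build_peq(rpat), len(rpat), rtext)
    if dist != edit_distance:  # pragma: no cover - internal consistency
        raise AssertionError("reverse scan disagrees with forward distance")
    return best_end_offset - consumed, best_end_offset


def _candidate_window(
    genome: Genome, position: int, read_len: int, threshold: int
) -> Optional[tuple[int, int]]:
    """Concatenated [start, end) of the verification window around a
    candidate, clamped to its chromosome; None if hopelessly out of range."""
    total = genome.total_length
    lo = position - threshold
    hi = position + read_len + threshold
    probe = min(max(position + read_len // 2, 0), total - 1)
    ci = genome.chrom_index(probe)
    cstart, cend = genome.chrom_bounds(ci)
    lo = max(lo, cstart)
    hi = min(hi, cend)
    if hi - lo < read_len - threshold:
        return None
    return lo, hi


@dataclass(slots=True)
class CandidateScore:
    """A non-rejected verification of one candidate (traceback deferred)."""

    candidate: Candidate
    edit_distance: int
    window_start: int  # concatenated coordinate of the window origin
    end_offset: int  # window offset one past the alignment end
    pattern: str  # read, or its reverse complement for '-' candidates


def score_candidates(
    read: str,
    candidates: Sequence[Candidate],
    genome: Genome,
    params: VerifyParams,
    batch_size: Optional[int] = None,
) -> list[CandidateScore]:
    """Banded verification of every candidate; REJECTs are dropped.

    Candidates are evaluated independently, so grouping them into batches
    of any size yields identical results; ``batch_size`` only sets the
    internal grouping.
    """
    if not candidates:
        return []
    t = params.error_threshold
    m = len(read)
    peq_fwd: Optional[dict[str, int]] = None
    peq_rev: Optional[dict[str, int]] = None
    scored: list[CandidateScore] = []
    groups: list[Sequence[Candidate]] = [candidates]
    if batch_size is not None and batch_size > 0:
        groups = [candidates[i : i + batch_size] for i in range(0, len(candidates), batch_size)]
    for group in groups:
        for cand in group:
            win = _candidate_window(genome, cand.position, m, t)
            if win is None:
                continue
            lo, hi = win
            window = genome.concat[lo:hi]
            if cand.strand == "+":
                if peq_fwd is None:
                    peq_fwd = build_peq(read)
                peq, pattern = peq_fwd, read
            else:
                if peq_rev is None:
                    peq_rev = build_peq(revcomp(read))
                peq, pattern = peq_rev, revcomp(read)
            res = banded_edit_distance(pattern, window, t, peq=peq)
            if res is None:
                continue
            dist, end = res
            scored.append(CandidateScore(cand, dist, lo, end, pattern))
    return scored


def finish_alignment(genome: Genome, cs: CandidateScore) -> AlignmentResult:
    """Trace back a scored candidate to exact reference coordinates."""
    lo = cs.window_start
    window = genome.concat[lo : lo + cs.end_offset]
    wstart, wend = traceback_positions(cs.pattern, window, cs.edit_distance, cs.end_offset)
    return AlignmentResult(
        candidate=cs.candidate,
        start=lo + wstart,
        end=lo + wend,
        strand=cs.candidate.strand,
        edit_distance=cs.edit_distance,
        score=(wend - wstart) - cs.edit_distance,
    )


def verify_candidates(
    read: str,
    candidates: Sequence[Candidate],
    genome: Genome,
    params: VerifyParams,
    batch_size: Optional[int] = None,
) -> VerifyOutcome:
    """Verify every candidate and pick the minimum-distance mapping.

    Returns the best alignment (ties broken toward the smallest reference
    coordinate), the runner-up distance, and the number of candidates
    attaining the minimum; all candidates rejected means unmapped.
    """
    scored = score_candidates(read, candidates, genome, params, batch_size=batch_size)
    if not scored:
        return VerifyOutcome(None, None, 0)
    scored.sort(key=lambda s: (s.edit_distance, s.candidate.position, s.candidate.strand))
    best = scored[0]
    num_best = sum(1 for s in scored if s.edit_distance == best.edit_distance)
    second = scored[1].edit_distance if len(scored) > 1 else None
    return VerifyOutcome(finish_alignment(genome, best), second, num_best)


def compute_mapq(
    best: AlignmentResult,
    second_best_distance: Optional[int],
    num_best: int,
    multiplicity: int = 1,
) -> int:
    """Deterministic MAPQ convention on [0, 60].

    Multiple equally good locations force 0; a sole candidate with no
    runner-up earns 60; otherwise the margin between runner-up and best
    distance scales the score (20 per edit of margin, capped at 60). MAPQ
    is monotone non-decreasing in the runner-up distance.
    """
    return mapq_from_distances(best.edit_distance, second_best_distance, num_best)


def mapq_from_distances(
    best_distance: int, second_best_distance: Optional[int], num_best: int
) -> int:
    """The MAPQ rule on raw distances (also applied at fragment level,
    where the distance is the summed edit distance of the two ends)."""
    if num_best >= 2:
        return 0
    if second_best_distance is None:
        return 60
    return max(0, min(60, 20 * (second_best_distance - best_distance)))


# ---------------------------------------------------------------------------
# Split (chimeric) mapping for Hi-C
# ---------------------------------------------------------------------------


def _encode(text: str) -> np.ndarray:
    raw = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    out = np.full(len(text), 4, dtype=np.int8)
    for base, code in _BASE_ORD.items():
        out[raw == ord(base)] = code
    return out


def _prefix_anchored_dp(
    pattern: str, text: str, threshold: int
) -> Optional[tuple[int, int, int]]:
    """Longest pattern prefix mappable into ``text`` within ``threshold``.

    Row-vectorized semi-global DP with free text start/end. Returns
    (prefix_len, edit_distance, text_end) for the longest prefix whose best
    alignment distance stays within the threshold, or None when even the
    first base cannot be placed.
    """
    n = len(text)
    if n == 0:
        return None
    tcodes = _encode(text)
    idx = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)
    best: Optional[tuple[int, int, int]] = None
    for i, ch in enumerate(pattern, start=1):
        code = _BASE_ORD.get(ch, 4)
        mismatch = (tcodes != code) | (code == 4)
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = i
        cur[1:] = np.minimum(prev[:-1] + mismatch, prev[1:] + 1)
        cur = np.minimum.accumulate(cur - idx) + idx
        row_min = int(cur.min())
        if row_min <= threshold:
            best = (i, row_min, int(cur.argmin()))
        else:
            break  # row minima are non-decreasing in the prefix length
        prev = cur
    return best


def split_map(
    read: str,
    candidates: Sequence[Candidate],
    genome: Genome,
    params: VerifyParams,
) -> Optional[AlignmentResult]:
    """Split mapping for reads whose full-length verification failed.

    For each candidate the longest prefix-anchored mapping within the band
    is found; the best candidate is the one maximizing score = mapped
    length - edit distance (ties toward the smallest reference start). If
    the mapped length misses ``min_split_length``, a second round maps the
    read after excluding its first ``split_5prime_skip`` bases and, on
    success, extends the mapping start backward by maximal exact matching.
    Pair constraints do not apply in this mode.
    """
    if not candidates:
        return None
    t = params.error_threshold
    skip = params.split_5prime_skip
    best_res: Optional[AlignmentResult] = None

    def consider(res: AlignmentResult) -> None:
        nonlocal best_res
        if best_res is None or (res.score, -res.start) > (best_res.score, -best_res.start):
            best_res = res

    for cand in candidates:
        win = _candidate_window(genome, cand.position, len(read), t)
        if win is None:
            continue
        lo, hi = win
        window = genome.concat[lo:hi]
        # Work in the read-forward frame: for '-' candidates the reverse
        # complement of the window makes the read map forward, so "read
        # prefix" means the same thing on both strands.
        text = window if cand.strand == "+" else revcomp(window)
        wlen = len(window)

        def to_ref(s: int, e: int) -> tuple[int, int]:
            if cand.strand == "+":
                return lo + s, lo + e
            return lo + (wlen - e), lo + (wlen - s)

        hit = _prefix_anchored_dp(read, text, t)
        if hit is not None:
            plen, dist, tend = hit
            if plen >= params.min_split_length:
                tstart, _ = traceback_positions(read[:plen], text[:tend], dist, tend)
                rs, re_ = to_ref(tstart, tend)
                consider(
                    AlignmentResult(cand, rs, re_, cand.strand, dist,
                                    score=plen - dist, is_split=True, clip5=0)
                )
                continue
        # Second round: exclude the first `skip` bases of the read.
        if len(read) <= skip:
            continue
        tail = read[skip:]
        hit2 = _prefix_anchored_dp(tail, text, t)
        if hit2 is None:
            continue
        plen2, dist2, tend2 = hit2
        if plen2 < params.min_split_length:
            continue
        tstart2, _ = traceback_positions(tail[:plen2], text[:tend2], dist2, tend2)
        # Backward maximal exact extension into the excluded 5' bases.
        ext = 0
        while ext < skip and tstart2 - ext - 1 >= 0 and text[tstart2 - ext - 1] == read[skip - ext - 1]:
            ext += 1
        rs, re_ = to_ref(tstart2 - ext, tend2)
        consider(
            AlignmentResult(cand, rs, re_, cand.strand, dist2,
                            score=(plen2 + ext) - dist2, is_split=True, clip5=skip - ext)
        )
    return best_res
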