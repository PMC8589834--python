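"""Adapter read-through trimming and whitelist-based barcode correction.

Trimming is overlap-based and adapter-agnostic: when an (sc)ATAC fragment
is shorter than the read length, the read runs into the adapter, and the
fragment appears as a prefix of R1 and a suffix of revcomp(R2). Two
non-overlapping seeds of length l_ovp/2 taken from R1's prefix locate the
overlap exactly; by the pigeonhole principle any true overlap of length
>= l_ovp with at most one mismatch leaves at least one seed exact, so the
overlap is always found. Verified overlaps (Hamming distance <= 1) trim
both reads to the fragment.

Barcode correction converts barcodes to 2-bit integers, counts whitelist
abundances over the observed data, enumerates all one-substitution
neighbors by bit masking, and corrects an off-list barcode to the
whitelisted neighbor with the highest posterior probability — the prior is
the neighbor's abundance and the likelihood of the mismatched base is its
sequencing-error probability from the quality score — when that posterior
reaches the acceptance threshold (default 90%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .io_formats import ReadPair, SequencedRead, revcomp

PathLike = Union[str, Path]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_DEC = "ACGT"


@dataclass(slots=True)
class TrimParams:
    """Adapter-trimming parameters.

    l_ovp: minimum overlap length; seeds are l_ovp // 2 long, so it must
    be at least 4 (shorter seeds would hit everywhere by chance).
    max_mismatch is fixed at 1 — the seeding scheme's guarantee covers
    exactly one mismatch.
    """

    l_ovp: int = 25
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.l_ovp < 4:
            raise ValueError("l_ovp must be >= 4")
        if self.max_mismatch != 1:
            raise ValueError("the seeding guarantee holds for max_mismatch=1 only")

    @property
    def seed_len(self) -> int:
        return self.l_ovp // 2


def _hamming_at_most(a: str, b: str, limit: int) -> Optional[int]:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return None
    return d


def trim_adapters(pair: ReadPair, params: Optional[TrimParams] = None) -> ReadPair:
    """Detect adapter read-through in a pair and trim to the fragment.

    The overlap between R1 and revcomp(R2) is located with two exact seeds
    from R1's prefix and verified at <= 1 Hamming mismatch; on success both
    reads are truncated to the overlap. Pairs without a qualifying overlap
    are returned unchanged.
    """
    params = params or TrimParams()
    if pair.r2 is None:
        return pair
    r1, r2 = pair.r1, pair.r2
    s = params.seed_len
    if len(r1.seq) < 2 * s or len(r2.seq) < params.l_ovp:
        return pair
    r2rc = revcomp(r2.seq)
    len1, len2 = len(r1.seq), len(r2.seq)
    best_f = None
    for offset in (0, s):
        seed = r1.seq[offset : offset + s]
        start = 0
        while True:
            p = r2rc.find(seed, start)
            if p == -1:
                break
            start = p + 1
            f = len2 - p + offset
            if f < params.l_ovp or f > min(len1, len2):
                continue
            if _hamming_at_most(r1.seq[:f], r2rc[len2 - f :], params.max_mismatch) is None:
                continue
            if best_f is None or f > best_f:
                best_f = f
    if best_f is None:
        return pair
    f = best_f  # trimming to a full-length overlap is a harmless no-op
    new_r1 = replace(r1, seq=r1.seq[:f], quals=r1.quals[:f] if r1.quals else None)
    new_r2 = replace(r2, seq=r2.seq[:f], quals=r2.quals[:f] if r2.quals else None)
    return ReadPair(new_r1, new_r2)


# ---------------------------------------------------------------------------
# Barcode whitelist and correction
# ---------------------------------------------------------------------------


def encode_barcode(seq: str) -> int:
    """2-bit encode an ACGT barcode (most significant bits first)."""
    val = 0
    for ch in seq:
        val = (val << 2) | _ENC[ch]
    return val


def decode_barcode(bits: int, length: int) -> str:
    out = []
    for i in range(length):
        out.append(_DEC[(bits >> (2 * (length - 1 - i))) & 3])
    return "".join(out)


def enumerate_neighbors(barcode_bits: int, length: int) -> list[tuple[int, int, str]]:
    """All 3*L single-substitution variants of a 2-bit encoded barcode.

    Returns (candidate_bits, mismatch_position, substituted_base) triples;
    the input itself is never among them.
    """
    out = []
    for i in range(length):
        shift = 2 * (length - 1 - i)
        orig = (barcode_bits >> shift) & 3
        for code in range(4):
            if code == orig:
                continue
            cand = barcode_bits ^ ((orig ^ code) << shift)
            out.append((cand, i, _DEC[code]))
    return out


class BarcodeWhitelist:
    """Bit-encoded whitelist with abundance counts.

    Abundance = pseudo-count 1 + number of exact whitelist matches seen in
    the observed barcode reads; the pseudo-count keeps legitimate rare
    barcodes from having a zero prior.
    """

    def __init__(self, barcodes: Iterable[str]):
        self.entries: dict[int, int] = {}
        self.barcode_length = -1
        for bc in barcodes:
            bc = bc.strip().upper()
            if not bc:
                continue
            if self.barcode_length < 0:
                self.barcode_length = len(bc)
            elif len(bc) != self.barcode_length:
                raise ValueError("mixed barcode lengths in whitelist")
            self.entries[encode_barcode(bc)] = 1
        if not self.entries:
            raise ValueError("empty whitelist")

    def __contains__(self, seq: str) -> bool:
        try:
            return encode_barcode(seq) in self.entries
        except KeyError:  # non-ACGT character
            return False

    def __len__(self) -> int:
        return len(self.entries)

    def abundance(self, seq: str) -> int:
        return self.entries.get(encode_barcode(seq), 0)

    def count_observation(self, seq: str) -> None:
        """Add one observed barcode read to the abundance counts (exact
        whitelist matches only)."""
        if len(seq) != self.barcode_length:
            return
        try:
            bits = encode_barcode(seq)
        except KeyError:
            return
        if bits in self.entries:
            self.entries[bits] += 1


def build_whitelist(
    path: PathLike, barcode_reads: Optional[Iterable[str]] = None
) -> BarcodeWhitelist:
    """Load a one-barcode-per-line whitelist and count abundances over an
    optional pass of observed barcode sequences."""
    with open(path) as fh:
        wl = BarcodeWhitelist(fh)
    if barcode_reads is not None:
        for seq in barcode_reads:
            wl.count_observation(seq.upper())
    return wl


def barcode_posteriors(
    observed: str, quals: str, whitelist: BarcodeWhitelist
) -> list[tuple[str, float]]:
    """Posterior probability of each whitelisted one-Hamming neighbor.

    For a neighbor c mismatching the observed barcode at position i,
    likelihood = (10^(-q_i/10)) / 3 with q_i the observed base quality, and
    prior proportional to abundance(c); posteriors are the normalized
    products and sum to 1 over the candidates. Sorted by decreasing
    posterior (ties: lexicographic barcode), deterministically.
    """
    if len(quals) != len(observed):
        raise ValueError("barcode quality length mismatch")
    length = whitelist.barcode_length
    weights: list[tuple[str, float]] = []
    n_pos = [i for i, ch in enumerate(observed) if ch not in _ENC]
    if len(n_pos) > 1:
        return []
    if n_pos:
        # a single ambiguous base: only substitutions there can reach the list
        i = n_pos[0]
        q = ord(quals[i]) - 33
        lik = (10.0 ** (-q / 10.0)) / 3.0
        for base in _DEC:
            cand = observed[:i] + base + observed[i + 1 :]
            bits = encode_barcode(cand)
            ab = whitelist.entries.get(bits)
            if ab:
                weights.append((cand, ab * lik))
    else:
        bits = encode_barcode(observed)
        for cand_bits, i, _base in enumerate_neighbors(bits, length):
            ab = whitelist.entries.get(cand_bits)
            if not ab:
                continue
            q = ord(quals[i]) - 33
            lik = (10.0 ** (-q / 10.0)) / 3.0
            weights.append((decode_barcode(cand_bits, length), ab * lik))
    total = sum(w for _, w in weights)
    if total == 0:
        return []
    posts = [(bc, w / total) for bc, w in weights]
    posts.sort(key=lambda x: (-x[1], x[0]))
    return posts


def correct_barcode(
    observed: str,
    quals: str,
    whitelist: BarcodeWhitelist,
    accept_threshold: float = 0.9,
) -> Optional[str]:
    """Correct an observed barcode onto the whitelist, or None (REJECT).

    On-list barcodes pass through unchanged; off-list barcodes are
    corrected to the highest-posterior one-Hamming whitelisted neighbor iff
    that posterior reaches ``accept_threshold``.
    """
    observed = observed.upper()
    if len(observed) != whitelist.barcode_length:
        return None
    if all(ch in _ENC for ch in observed) and encode_barcode(observed) in whitelist.entries:
        return observed
    posts = barcode_posteriors(observed, quals, whitelist)
    if not posts:
        return None
    best, p = posts[0]
    return best if p >= accept_threshold else None
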