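"""Double-strand minimizer extraction and the reference hash-table index.

A minimizer is the k-mer with minimum hashed value within a window of w
consecutive k-mers; extracting minimizers from both the reference and the
reads turns exact seed matching into a sparse, shift-stable sketch
comparison. Keys are computed by an invertible integer mix of the 2-bit
encoding, canonicalized over both strands: the strand whose encoding hashes
lower wins and is recorded, and k-mers whose two hashes are equal are
skipped (impossible for odd k, where a k-mer can never equal its own
reverse complement and the hash is a bijection).

The index maps each key to its occurrence list on the concatenated
reference, stored sorted by position so the candidate supplement step can
binary-search a genomic window. Keys occurring more than ``max_occ`` times
are masked at query time, not build time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np

from .io_formats import Genome, GenomeSequence

PathLike = Union[str, Path]

_MAGIC = b"CAIX\x01"
_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(slots=True)
class MinimizerParams:
    """Sketch parameters.

    k: k-mer length (<= 28 so the 2-bit encoding fits one machine word).
    w: window size in k-mers.
    max_occ: occurrence threshold; keys occurring strictly more often on
        the reference are masked during query.
    hash_name: "mix" (default invertible finalizing hash) or "identity"
        (test hook for hand-checkable examples).
    """

    k: int = 17
    w: int = 7
    max_occ: int = 500
    hash_name: str = "mix"

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 28:
            raise ValueError(f"k={self.k} outside [1, 28]")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if self.max_occ < 1:
            raise ValueError("max_occ must be >= 1")
        if self.hash_name not in ("mix", "identity"):
            raise ValueError(f"unknown hash {self.hash_name!r}")


class Minimizer(NamedTuple):
    key: int
    pos: int
    strand: str  # which strand's encoding achieved the minimum


@dataclass(slots=True)
class Minimizers:
    """Column-oriented minimizer set of one sequence, sorted by position."""

    pos: np.ndarray  # int64, k-mer start on the source sequence
    key: np.ndarray  # uint64, canonical hashed key
    strand: np.ndarray  # uint8, 0 = forward encoding won, 1 = reverse

    def __len__(self) -> int:
        return len(self.pos)

    def to_list(self) -> list[Minimizer]:
        return [
            Minimizer(int(k), int(p), "-" if s else "+")
            for p, k, s in zip(self.pos, self.key, self.strand)
        ]


def encode_bases(seq: str) -> np.ndarray:
    """2-bit base codes (A=0, C=1, G=2, T=3); anything else maps to 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def _mix_hash(key: np.ndarray, bits: int) -> np.ndarray:
    """Invertible 64-bit finalizing mix, masked to ``bits`` bits.

    Murmur-style avalanche; being a bijection on [0, 2^bits) it preserves
    the skip rule's meaning (equal hashes iff equal k-mers).
    """
    mask = np.uint64((1 << bits) - 1)
    key = key.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        key = (~key + (key << np.uint64(21))) & mask
        key = key ^ (key >> np.uint64(24))
        key = (key + (key << np.uint64(3)) + (key << np.uint64(8))) & mask
        key = key ^ (key >> np.uint64(14))
        key = (key + (key << np.uint64(2)) + (key << np.uint64(4))) & mask
        key = key ^ (key >> np.uint64(28))
        key = (key + (key << np.uint64(31))) & mask
    return key


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward and reverse-complement 2-bit k-mer values plus validity mask."""
    n = len(codes) - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty, np.empty(0, dtype=bool)
    codes64 = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    with np.errstate(over="ignore"):
        for i in range(k):
            fwd = (fwd << two) | (codes64[i : i + n] & np.uint64(3))
            rev = (rev << two) | ((np.uint64(3) - codes64[k - 1 - i : k - 1 - i + n]) & np.uint64(3))
    invalid = codes >= 4
    if invalid.any():
        bad = np.convolve(invalid.astype(np.int32), np.ones(k, dtype=np.int32), "valid") > 0
        valid = ~bad
    else:
        valid = np.ones(n, dtype=bool)
    return fwd, rev, valid


def extract_minimizers(seq: str, params: MinimizerParams) -> Minimizers:
    """Extract double-strand minimizers of ``seq``.

    For every window of w consecutive valid k-mers, all positions achieving
    the minimum canonical key are reported once. k-mers containing N are
    invalid and break windows; strand-ambiguous k-mers (equal forward and
    reverse-complement hashes) are never selected.
    """
    k, w = params.k, params.w
    codes = encode_bases(seq)
    fwd, rev, valid = _kmer_values(codes, k)
    nk = len(fwd)
    if nk < w:
        return Minimizers(
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint8)
        )
    if params.hash_name == "mix":
        hf = _mix_hash(fwd, 2 * k)
        hr = _mix_hash(rev, 2 * k)
    else:
        hf, hr = fwd, rev
    strand = (hr < hf).astype(np.uint8)
    keys = np.minimum(hf, hr)
    skip = hf == hr
    keys = keys.copy()
    keys[skip | ~valid] = _SENTINEL

    sw = np.lib.stride_tricks.sliding_window_view
    keymat = sw(keys, w)
    if valid.all():
        win_ok = np.ones(len(keymat), dtype=bool)
    else:
        win_ok = ~sw(~valid, w).any(axis=1)
    wmin = keymat.min(axis=1)
    sel = win_ok[:, None] & (keymat == wmin[:, None]) & (wmin != _SENTINEL)[:, None]
    widx, col = np.nonzero(sel)
    pos = np.unique(widx + col)
    return Minimizers(pos.astype(np.int64), keys[pos], strand[pos])


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------


class Anchors:
    """Column-oriented anchor set: exact minimizer hits of a read.

    x = minimizer start on the concatenated reference, y = minimizer start
    on the read, strand = relative orientation (0: read forward strand
    matches reference, 1: reverse complement matches).
    """

    __slots__ = ("x", "y", "strand")

    def __init__(self, x: np.ndarray, y: np.ndarray, strand: np.ndarray):
        self.x = x
        self.y = y
        self.strand = strand

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def empty(cls) -> "Anchors":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z.copy(), np.empty(0, dtype=np.uint8))

    @classmethod
    def from_lists(cls, triples: Sequence[tuple[int, int, int]]) -> "Anchors":
        if not triples:
            return cls.empty()
        arr = np.asarray(triples, dtype=np.int64)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2].astype(np.uint8))


class MinimizerIndex:
    """Hash-table index from minimizer key to sorted reference occurrences."""

    def __init__(
        self,
        params: MinimizerParams,
        keys: np.ndarray,
        starts: np.ndarray,
        positions: np.ndarray,
        strands: np.ndarray,
        chromsizes: list[tuple[str, int]],
        genome_digest: str,
        genome: Optional[Genome] = None,
    ):
        self.params = params
        self.keys = keys  # sorted unique keys
        self.starts = starts  # len(keys)+1 offsets into positions/strands
        self.positions = positions  # concatenated-genome coordinates, sorted per key
        self.strands = strands
        self.chromsizes = chromsizes
        self.genome_digest = genome_digest
        # The reference itself travels with the index so that mapping needs
        # only the index file (verification re-reads genome windows).
        self.genome = genome

    @property
    def num_keys(self) -> int:
        return len(self.keys)

    def _slot(self, key: int) -> int:
        i = int(np.searchsorted(self.keys, np.uint64(key)))
        if i < len(self.keys) and self.keys[i] == np.uint64(key):
            return i
        return -1

    def count(self, key: int) -> int:
        i = self._slot(key)
        if i < 0:
            return 0
        return int(self.starts[i + 1] - self.starts[i])

    def occurrences(self, key: int) -> tuple[np.ndarray, np.ndarray]:
        """Sorted reference positions and strands of a key (empty if absent)."""
        i = self._slot(key)
        if i < 0:
            z = np.empty(0, dtype=np.int64)
            return z, np.empty(0, dtype=np.uint8)
        a, b = int(self.starts[i]), int(self.starts[i + 1])
        return self.positions[a:b], self.strands[a:b]

    def save(self, path: PathLike) -> None:
        header = {
            "k": self.params.k,
            "w": self.params.w,
            "max_occ": self.params.max_occ,
            "hash_name": self.params.hash_name,
            "chromsizes": self.chromsizes,
            "genome_digest": self.genome_digest,
        }
        hjson = json.dumps(header, sort_keys=True).encode()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(len(hjson).to_bytes(8, "little"))
            fh.write(hjson)
            for arr in (self.keys, self.starts, self.positions, self.strands):
                np.save(fh, arr)
            seq = self.genome.concat if self.genome is not None else ""
            np.save(fh, np.frombuffer(seq.encode("ascii"), dtype=np.uint8))

    @classmethod
    def load(cls, path: PathLike) -> "MinimizerIndex":
        with open(path, "rb") as fh:
            magic = fh.read(len(_MAGIC))
            if magic != _MAGIC:
                raise ValueError(f"{path}: not a chromalign index file")
            hlen = int.from_bytes(fh.read(8), "little")
            header = json.loads(fh.read(hlen))
            keys = np.load(fh)
            starts = np.load(fh)
            positions = np.load(fh)
            strands = np.load(fh)
            seq_bytes = np.load(fh)
        params = MinimizerParams(
            k=header["k"], w=header["w"], max_occ=header["max_occ"],
            hash_name=header["hash_name"],
        )
        chromsizes = [(str(n), int(s)) for n, s in header["chromsizes"]]
        genome = None
        if len(seq_bytes):
            concat = seq_bytes.tobytes().decode("ascii")
            seqs = []
            at = 0
            for name, size in chromsizes:
                seqs.append(GenomeSequence(name, concat[at : at + size]))
                at += size
            genome = Genome(seqs)
        return cls(
            params, keys, starts, positions, strands, chromsizes,
            header["genome_digest"], genome,
        )


def genome_digest(genome: Genome) -> str:
    h = hashlib.sha256()
    for s in genome.sequences:
        h.update(s.name.encode())
        h.update(b"\x00")
        h.update(s.seq.encode())
        h.update(b"\x00")
    return h.hexdigest()


def build_index(genome: Genome, params: Optional[MinimizerParams] = None) -> MinimizerIndex:
    """Build the minimizer index of a genome in concatenated coordinates."""
    params = params or MinimizerParams()
    all_keys, all_pos, all_strand = [], [], []
    for seq in genome.sequences:
        mins = extract_minimizers(seq.seq, params)
        if len(mins):
            all_keys.append(mins.key)
            all_pos.append(mins.pos + seq.offset)
            all_strand.append(mins.strand)
    if all_keys:
        keys = np.concatenate(all_keys)
        pos = np.concatenate(all_pos)
        strand = np.concatenate(all_strand)
    else:
        keys = np.empty(0, dtype=np.uint64)
        pos = np.empty(0, dtype=np.int64)
        strand = np.empty(0, dtype=np.uint8)
    order = np.lexsort((pos, keys))
    keys, pos, strand = keys[order], pos[order], strand[order]
    ukeys, idx, counts = np.unique(keys, return_index=True, return_counts=True)
    starts = np.concatenate([idx, [len(keys)]]).astype(np.int64)
    chromsizes = [(s.name, len(s.seq)) for s in genome.sequences]
    return MinimizerIndex(
        params, ukeys, starts, pos, strand, chromsizes, genome_digest(genome), genome
    )


def query_index(index: MinimizerIndex, read_minimizers: Minimizers) -> Anchors:
    """Anchors of a read: one per occurrence of each unmasked minimizer key.

    Keys occurring more than ``max_occ`` times on the reference contribute
    nothing (the high-frequency mask, applied at query time).
    """
    max_occ = index.params.max_occ
    xs, ys, ss = [], [], []
    for p, key, rstrand in zip(read_minimizers.pos, read_minimizers.key, read_minimizers.strand):
        pos, ref_strand = index.occurrences(int(key))
        n = len(pos)
        if n == 0 or n > max_occ:
            continue
        xs.append(pos)
        ys.append(np.full(n, p, dtype=np.int64))
        ss.append(ref_strand ^ rstrand)
    if not xs:
        return Anchors.empty()
    return Anchors(np.concatenate(xs), np.concatenate(ys), np.concatenate(ss))
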