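"""Readers and writers for the on-disk formats the pipeline touches.

Covers FASTA references, (optionally gzipped) FASTQ read streams with
synchronized mates and barcode reads, and the three output flavors:

* BED for single-end mappings,
* BEDPE/fragment lines for paired fragments (outermost coordinates, with a
  barcode column for single-cell data),
* the 4DN pairs format for Hi-C contacts.

Coordinates are 0-based half-open everywhere internally and in BED/BEDPE;
pairs positions are written 1-based per the 4DN convention.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC ambiguity codes (and anything else non-ACGT) collapse to N.
_CLEAN = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVUryswkmbdhvu"}
)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_maybe_gzip(path: PathLike, mode: str = "rt") -> IO:
    """Open a text file, transparently decompressing gzip (magic-byte sniff)."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class GenomeSequence:
    """One reference chromosome.

    ``offset`` is the cumulative 0-based start of this chromosome in the
    concatenated genome coordinate space used by the index and the
    candidate engine.
    """

    name: str
    seq: str
    offset: int = 0

    def __len__(self) -> int:
        return len(self.seq)


class Genome:
    """A reference genome with concatenated-coordinate bookkeeping.

    The minimizer index and candidate engine work in a single concatenated
    coordinate space; output records need (chrom, local) coordinates. The
    conversion is an exact bijection over all valid positions.
    """

    def __init__(self, sequences: Sequence[GenomeSequence]):
        if not sequences:
            raise ValueError("empty genome")
        names = [s.name for s in sequences]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome")
        offset = 0
        for s in sequences:
            s.offset = offset
            offset += len(s.seq)
        self.sequences = list(sequences)
        self.names = names
        self.offsets = np.array([s.offset for s in sequences], dtype=np.int64)
        self.lengths = np.array([len(s.seq) for s in sequences], dtype=np.int64)
        self.total_length = int(offset)
        self.concat = "".join(s.seq for s in sequences)
        self._rank = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return self.total_length

    def chrom_index(self, pos: int) -> int:
        """Index of the chromosome containing concatenated position ``pos``."""
        if not 0 <= pos < self.total_length:
            raise IndexError(f"position {pos} outside genome")
        return int(np.searchsorted(self.offsets, pos, side="right")) - 1

    def to_local(self, pos: int) -> tuple[str, int]:
        i = self.chrom_index(pos)
        return self.names[i], int(pos - self.offsets[i])

    def to_concat(self, name: str, local: int) -> int:
        i = self._rank[name]
        if not 0 <= local < self.lengths[i]:
            raise IndexError(f"{name}:{local} outside chromosome")
        return int(self.offsets[i] + local)

    def chrom_rank(self, name: str) -> int:
        """Reference-order rank of a chromosome, for deterministic sorting."""
        return self._rank[name]

    def chrom_bounds(self, chrom_idx: int) -> tuple[int, int]:
        """Concatenated [start, end) of a chromosome."""
        start = int(self.offsets[chrom_idx])
        return start, start + int(self.lengths[chrom_idx])


@dataclass(slots=True)
class SequencedRead:
    name: str
    seq: str
    quals: Optional[str] = None
    barcode_seq: Optional[str] = None
    barcode_quals: Optional[str] = None

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(f"read {self.name}: quality/sequence length mismatch")
        if (
            self.barcode_seq is not None
            and self.barcode_quals is not None
            and len(self.barcode_quals) != len(self.barcode_seq)
        ):
            raise ValueError(f"read {self.name}: barcode quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class ReadPair:
    r1: SequencedRead
    r2: Optional[SequencedRead] = None

    @property
    def is_paired(self) -> bool:
        return self.r2 is not None


@dataclass(slots=True)
class MappingRecord:
    """A verified mapping of one read or fragment.

    ``start``/``end`` are 0-based half-open local chromosome coordinates.
    For paired data a record represents the whole fragment (outermost
    coordinates of the two ends).
    """

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    edit_distance: int = 0
    barcode: Optional[str] = None
    is_split: bool = False
    num_duplicates: int = 1
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"MAPQ {self.mapq} outside [0, 60]")


@dataclass(slots=True)
class ContactRecord:
    """A Hi-C contact: two mapped ends of one read pair.

    Positions are 0-based 5'-end coordinates; writers emit them 1-based.
    Stored in upper-triangle order (chrom1 <= chrom2 in reference order,
    pos1 <= pos2 on ties).
    """

    name: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    mapq: int = 0
    num_duplicates: int = 1


# ---------------------------------------------------------------------------
# FASTA / FASTQ readers
# ---------------------------------------------------------------------------


def clean_sequence(seq: str) -> str:
    """Upper-case and collapse non-ACGTN characters to N."""
    return seq.upper().translate(_CLEAN)


def read_fasta(path: PathLike) -> list[GenomeSequence]:
    """Read a (possibly gzipped) FASTA into GenomeSequence records.

    Sequences are upper-cased, ambiguity codes become N, and concatenated
    offsets are assigned in input order. Empty files and duplicate
    chromosome names are hard errors.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    offset = 0
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = clean_sequence(str(rec.seq))
            records.append(GenomeSequence(rec.id, seq, offset))
            offset += len(seq)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_genome(path: PathLike) -> Genome:
    return Genome(read_fasta(path))


def write_fasta(sequences: Sequence[GenomeSequence], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


def strip_pair_suffix(name: str) -> str:
    """Drop space-delimited comments and trailing /1 or /2 from a read name."""
    name = name.split(None, 1)[0]
    if name.endswith(("/1", "/2")):
        name = name[:-2]
    return name


def _fastq_records(path: PathLike) -> Iterator[tuple[str, str, str]]:
    with _open_maybe_gzip(path) as fh:
        yield from FastqGeneralIterator(fh)


def stream_read_pairs(
    path1: PathLike,
    path2: Optional[PathLike] = None,
    barcode_path: Optional[PathLike] = None,
) -> Iterator[ReadPair]:
    """Stream synchronized read pairs (or single-end reads) from FASTQ.

    Mate and barcode files must be record-for-record synchronized with
    ``path1``; a name mismatch or unequal record count is a hard error
    naming the offending record index.
    """
    it1 = _fastq_records(path1)
    it2 = _fastq_records(path2) if path2 is not None else None
    itb = _fastq_records(barcode_path) if barcode_path is not None else None
    sentinel = object()
    for idx, (t1, s1, q1) in enumerate(it1):
        n1 = strip_pair_suffix(t1)
        r1 = SequencedRead(n1, s1.upper(), q1)
        if itb is not None:
            recb = next(itb, sentinel)
            if recb is sentinel:
                raise ValueError(f"barcode FASTQ ended early at record {idx}")
            tb, sb, qb = recb
            if strip_pair_suffix(tb) != n1:
                raise ValueError(
                    f"read/barcode name mismatch at record {idx}: {n1!r} vs {strip_pair_suffix(tb)!r}"
                )
            r1.barcode_seq = sb.upper()
            r1.barcode_quals = qb
        r2 = None
        if it2 is not None:
            rec2 = next(it2, sentinel)
            if rec2 is sentinel:
                raise ValueError(f"mate FASTQ ended early at record {idx}")
            t2, s2, q2 = rec2
            n2 = strip_pair_suffix(t2)
            if n2 != n1:
                raise ValueError(f"mate name mismatch at record {idx}: {n1!r} vs {n2!r}")
            r2 = SequencedRead(n2, s2.upper(), q2)
        yield ReadPair(r1, r2)
    for label, it in (("mate", it2), ("barcode", itb)):
        if it is not None and next(it, sentinel) is not sentinel:
            raise ValueError(f"{label} FASTQ has extra records beyond R1")


def write_fastq(reads: Sequence[SequencedRead], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.quals if r.quals is not None else "I" * len(r.seq)
            fh.write(f"@{r.name}\n{r.seq}\n+\n{quals}\n")


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def _check_sorted_records(records: Sequence[MappingRecord], chrom_rank) -> None:
    prev = None
    for rec in records:
        key = (chrom_rank(rec.chrom), rec.start, rec.end)
        if prev is not None and key < prev:
            raise ValueError("records are not coordinate-sorted")
        prev = key


def _write_interval_lines(
    records: Sequence[MappingRecord], path: PathLike, chrom_rank
) -> None:
    _check_sorted_records(records, chrom_rank)
    with open(path, "w") as fh:
        for rec in records:
            fields = [rec.chrom, str(rec.start), str(rec.end)]
            if rec.barcode is not None:
                fields.append(rec.barcode)
            fields.append(str(rec.num_duplicates))
            fields.append(rec.strand)
            fh.write("\t".join(fields) + "\n")


def write_bed(
    records: Sequence[MappingRecord], path: PathLike, chrom_rank=None
) -> None:
    """Write single-end mappings as BED: chrom, start, end, [barcode],
    duplicate count, strand. Input must be deduplicated and sorted."""
    _write_interval_lines(records, path, chrom_rank or (lambda c: c))


def write_bedpe(
    records: Sequence[MappingRecord], path: PathLike, chrom_rank=None
) -> None:
    """Write paired fragments (outermost coordinates of each pair), one line
    per fragment, same column layout as :func:`write_bed`."""
    _write_interval_lines(records, path, chrom_rank or (lambda c: c))


def orient_contact(rec: ContactRecord, chrom_rank) -> ContactRecord:
    """Return the contact in upper-triangle orientation."""
    k1 = (chrom_rank(rec.chrom1), rec.pos1)
    k2 = (chrom_rank(rec.chrom2), rec.pos2)
    if k2 < k1:
        return ContactRecord(
            rec.name, rec.chrom2, rec.pos2, rec.strand2,
            rec.chrom1, rec.pos1, rec.strand1, rec.mapq, rec.num_duplicates,
        )
    return rec


def write_pairs(
    records: Sequence[ContactRecord],
    path: PathLike,
    chromsizes: Sequence[tuple[str, int]],
) -> None:
    """Write Hi-C contacts in 4DN pairs format (1-based, upper triangle).

    ``records`` must already be upper-triangle oriented and sorted by
    (chrom1, pos1, chrom2, pos2) in reference chromosome order.
    """
    rank = {name: i for i, (name, _) in enumerate(chromsizes)}
    prev = None
    for rec in records:
        k1 = (rank[rec.chrom1], rec.pos1)
        k2 = (rank[rec.chrom2], rec.pos2)
        if k2 < k1:
            raise ValueError(f"contact {rec.name} violates upper-triangle convention")
        key = (*k1, *k2)
        if prev is not None and key < prev:
            raise ValueError("contacts are not coordinate-sorted")
        prev = key
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#shape: upper triangle\n")
        for name, size in chromsizes:
            fh.write(f"#chromsize: {name} {size}\n")
        fh.write("#columns: readID chr1 pos1 chr2 pos2 strand1 strand2\n")
        for rec in records:
            fh.write(
                f"{rec.name}\t{rec.chrom1}\t{rec.pos1 + 1}\t{rec.chrom2}\t"
                f"{rec.pos2 + 1}\t{rec.strand1}\t{rec.strand2}\n"
            )
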