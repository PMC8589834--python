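"""Duplicate removal, coordinate sorting, and the low-memory external sort.

Two fragments are PCR/optical duplicates when their mapping coordinates
(both endpoints and strand) coincide — and, at cell level, their corrected
cell barcode too, so identical fragments from different cells are kept
apart. The in-memory path sorts all records and collapses equal keys in
one scan; the low-memory path sorts fixed-size chunks, spills them to
temporary files, and k-way merges the spills, producing byte-identical
output to the in-memory path.
"""

from __future__ import annotations

import heapq
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence, Union

from .io_formats import ContactRecord, MappingRecord

PathLike = Union[str, Path]
ChromRank = Callable[[str], int]

_NONE = "\\N"


def _default_rank(chrom: str) -> int:
    raise ValueError(
        "a chrom_rank function (reference chromosome order) is required"
    )


def resolve_level(records: Sequence[MappingRecord], level: str) -> str:
    """Resolve the 'auto' dedup level: cell when barcodes are present."""
    if level == "auto":
        has_bc = any(r.barcode is not None for r in records)
        return "cell" if has_bc else "bulk"
    if level not in ("bulk", "cell"):
        raise ValueError(f"unknown dedup level {level!r}")
    return level


def _sort_key(rec: MappingRecord, rank: ChromRank):
    # Total order so the in-memory and external paths pick the same
    # representative for every duplicate group.
    return (
        rank(rec.chrom), rec.start, rec.end, rec.strand,
        rec.barcode or "", rec.mapq, rec.edit_distance, rec.name or "",
    )


def duplicate_key(rec: MappingRecord, level: str):
    if level == "cell":
        return (rec.chrom, rec.start, rec.end, rec.strand, rec.barcode)
    return (rec.chrom, rec.start, rec.end, rec.strand)


def _collapse(sorted_records: Iterable[MappingRecord], level: str) -> list[MappingRecord]:
    out: list[MappingRecord] = []
    cur: Optional[MappingRecord] = None
    cur_key = None
    for rec in sorted_records:
        key = duplicate_key(rec, level)
        if cur is not None and key == cur_key:
            cur.num_duplicates += rec.num_duplicates
        else:
            if cur is not None:
                out.append(cur)
            cur = MappingRecord(
                rec.chrom, rec.start, rec.end, rec.strand, rec.mapq,
                rec.edit_distance, rec.barcode, rec.is_split, rec.num_duplicates,
                rec.name,
            )
            cur_key = key
    if cur is not None:
        out.append(cur)
    return out


def remove_duplicates(
    records: Sequence[MappingRecord],
    level: str = "auto",
    chrom_rank: Optional[ChromRank] = None,
) -> list[MappingRecord]:
    """Collapse duplicate fragments; output sorted by (chrom, start, end).

    ``level`` is 'bulk', 'cell', or 'auto' (cell when barcodes present).
    Each output record's num_duplicates sums the collapsed inputs, so the
    total count is conserved. Requesting cell level without barcodes is a
    hard error.
    """
    rank = chrom_rank or _default_rank
    level = resolve_level(records, level)
    if level == "cell":
        missing = [r for r in records if r.barcode is None]
        if missing:
            raise ValueError("cell-level deduplication requires barcodes on every record")
    ordered = sorted(records, key=lambda r: _sort_key(r, rank))
    return _collapse(ordered, level)


# ---------------------------------------------------------------------------
# External sort
# ---------------------------------------------------------------------------


def _serialize(rec: MappingRecord) -> str:
    return "\t".join(
        (
            rec.chrom, str(rec.start), str(rec.end), rec.strand, str(rec.mapq),
            str(rec.edit_distance), rec.barcode if rec.barcode is not None else _NONE,
            "1" if rec.is_split else "0", str(rec.num_duplicates),
            rec.name if rec.name is not None else _NONE,
        )
    )


def _deserialize(line: str) -> MappingRecord:
    f = line.rstrip("\n").split("\t")
    return MappingRecord(
        chrom=f[0], start=int(f[1]), end=int(f[2]), strand=f[3], mapq=int(f[4]),
        edit_distance=int(f[5]), barcode=None if f[6] == _NONE else f[6],
        is_split=f[7] == "1", num_duplicates=int(f[8]),
        name=None if f[9] == _NONE else f[9],
    )


def _read_spill(path: Path) -> Iterator[MappingRecord]:
    with open(path) as fh:
        for line in fh:
            yield _deserialize(line)


@dataclass(slots=True)
class ExternalSortResult:
    records: list[MappingRecord]
    num_spills: int


def external_sort_dedup(
    records: Iterable[MappingRecord],
    level: str = "auto",
    chrom_rank: Optional[ChromRank] = None,
    chunk_size: int = 100_000,
    tmpdir: Optional[PathLike] = None,
) -> ExternalSortResult:
    """Deduplicate via sorted spill files and a k-way merge.

    ``chunk_size`` is the memory budget in records per chunk. The output
    (records and their order) is byte-identical to
    :func:`remove_duplicates`; when everything fits in one chunk no spill
    file is written.
    """
    rank = chrom_rank or _default_rank
    chunks: list[list[MappingRecord]] = []
    buf: list[MappingRecord] = []
    has_bc = False
    any_missing_bc = False
    for rec in records:
        has_bc = has_bc or rec.barcode is not None
        any_missing_bc = any_missing_bc or rec.barcode is None
        buf.append(rec)
        if len(buf) >= chunk_size:
            chunks.append(buf)
            buf = []
    if buf:
        chunks.append(buf)
    if level == "auto":
        level = "cell" if has_bc else "bulk"
    elif level not in ("bulk", "cell"):
        raise ValueError(f"unknown dedup level {level!r}")
    if level == "cell" and any_missing_bc:
        raise ValueError("cell-level deduplication requires barcodes on every record")

    key = lambda r: _sort_key(r, rank)
    if len(chunks) <= 1:
        ordered = sorted(chunks[0], key=key) if chunks else []
        return ExternalSortResult(_collapse(ordered, level), 0)

    with tempfile.TemporaryDirectory(dir=tmpdir) as td:
        paths = []
        for i, chunk in enumerate(chunks):
            chunk.sort(key=key)
            path = Path(td) / f"spill_{i:05d}.tsv"
            try:
                with open(path, "w") as fh:
                    for rec in chunk:
                        fh.write(_serialize(rec) + "\n")
            except OSError as exc:
                raise OSError(f"cannot write spill file in {td}: {exc}") from exc
            paths.append(path)
        merged = heapq.merge(*(_read_spill(p) for p in paths), key=key)
        collapsed = _collapse(merged, level)
    return ExternalSortResult(collapsed, len(paths))


# ---------------------------------------------------------------------------
# Hi-C contact deduplication
# ---------------------------------------------------------------------------


def _contact_sort_key(rec: ContactRecord, rank: ChromRank):
    return (
        rank(rec.chrom1), rec.pos1, rank(rec.chrom2), rec.pos2,
        rec.strand1, rec.strand2, rec.mapq, rec.name,
    )


def remove_duplicate_contacts(
    records: Sequence[ContactRecord], chrom_rank: ChromRank
) -> list[ContactRecord]:
    """Collapse Hi-C contacts duplicated on both ends jointly (positions
    and strands of the two sides); output upper-triangle sorted."""
    ordered = sorted(records, key=lambda r: _contact_sort_key(r, chrom_rank))
    out: list[ContactRecord] = []
    cur: Optional[ContactRecord] = None
    cur_key = None
    for rec in ordered:
        key = (rec.chrom1, rec.pos1, rec.strand1, rec.chrom2, rec.pos2, rec.strand2)
        if cur is not None and key == cur_key:
            cur.num_duplicates += rec.num_duplicates
        else:
            if cur is not None:
                out.append(cur)
            cur = ContactRecord(
                rec.name, rec.chrom1, rec.pos1, rec.strand1,
                rec.chrom2, rec.pos2, rec.strand2, rec.mapq, rec.num_duplicates,
            )
            cur_key = key
    if cur is not None:
        out.append(cur)
    return out
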