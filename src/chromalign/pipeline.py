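"""End-to-end drivers wiring the modules into ChIP / ATAC / Hi-C presets.

The per-read flow follows the mapping workflow: (trim) -> extract
minimizers -> candidate cache lookup -> (index query -> candidate
generation -> mate-rescue supplement) -> banded verification -> (split
mapping for Hi-C) -> barcode correction -> deduplication -> output.

Presets:
  chip  — single- or paired-end, fragment output, pair constraints on.
  atac  — chip plus adapter read-through trimming, barcode correction
          against a whitelist, and an optional Tn5 coordinate shift.
  hic   — per-end mapping that ignores pair constraints (fragment length,
          strandness), split-alignment fallback, 4DN pairs output.

Determinism: the candidate/cache stage runs in input order (the cache is
order-dependent by design), while verification is a pure function fanned
out over a thread pool with order-preserving collection — so outputs are
byte-identical for any thread count and across repeated runs.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .candidate_engine import (
    Candidate,
    CandidateCache,
    CandidateParams,
    MinimizerVector,
    best_candidate,
    generate_candidates,
    pair_filter,
    supplement_candidates,
)
from .io_formats import (
    ContactRecord,
    Genome,
    MappingRecord,
    ReadPair,
    orient_contact,
    stream_read_pairs,
    write_bed,
    write_bedpe,
    write_pairs,
)
from .minimizer_index import MinimizerIndex, Minimizers, extract_minimizers, query_index
from .postprocess import (
    external_sort_dedup,
    remove_duplicate_contacts,
    remove_duplicates,
)
from .preprocess import TrimParams, build_whitelist, correct_barcode, trim_adapters
from .verify_align import (
    VerifyParams,
    compute_mapq,
    finish_alignment,
    mapq_from_distances,
    score_candidates,
    split_map,
    verify_candidates,
)

logger = logging.getLogger("chromalign")

PathLike = Union[str, Path]

PRESETS = ("chip", "atac", "hic")


@dataclass
class PipelineConfig:
    """All module parameter blocks plus the preset switches."""

    preset: str = "chip"
    minimizer_k: Optional[int] = None  # informational; the index fixes k/w
    candidate: CandidateParams = field(default_factory=CandidateParams)
    verify: VerifyParams = field(default_factory=VerifyParams)
    trim: TrimParams = field(default_factory=TrimParams)
    trim_adapters: Optional[bool] = None  # default: on for atac only
    barcode_whitelist: Optional[str] = None
    bc_threshold: float = 0.9
    dedup_level: str = "auto"  # bulk | cell | auto (cell when barcoded)
    threads: int = 1
    batch_size: int = 2000
    use_cache: bool = True
    always_supplement: bool = False
    tn5_shift: bool = False  # shift fragment ends +4/-5 (ATAC convention)
    low_memory: bool = False
    dedup_chunk_size: int = 100_000
    seed: int = 0  # reserved for randomized fixture paths; mapping is deterministic

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.preset == "hic" and self.barcode_whitelist is not None:
            raise ValueError("the hic preset does not take a barcode whitelist")
        if self.trim_adapters is None:
            self.trim_adapters = self.preset == "atac"
        if self.preset == "hic" and self.trim_adapters:
            raise ValueError("adapter read-through trimming applies to chip/atac only")
        # One edit budget shared by candidate merging and verification.
        self.verify.error_threshold = self.candidate.error_threshold
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


@dataclass
class RunReport:
    preset: str = ""
    paired: bool = False
    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    barcode_rejected: int = 0
    cache_hits: int = 0
    cache_misses: int = 0
    cache_updates: int = 0
    records_before_dedup: int = 0
    records_after_dedup: int = 0
    duplicate_rate: float = 0.0
    dedup_level: str = ""
    outputs: dict = field(default_factory=dict)
    per_read: Optional[list] = None

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "per_read"}
        return d

    def conserved(self) -> bool:
        return self.mapped + self.unmapped + self.barcode_rejected == self.total


@dataclass(slots=True)
class _EndState:
    seq: str
    minimizers: Optional[Minimizers]
    candidates: list


@dataclass(slots=True)
class _PairState:
    name: str
    e1: _EndState
    e2: Optional[_EndState]
    barcode: Optional[str]


class _Mapper:
    def __init__(self, index: MinimizerIndex, config: PipelineConfig):
        if index.genome is None:
            raise ValueError("index carries no reference sequence; rebuild it")
        self.index = index
        self.genome: Genome = index.genome
        self.config = config
        self.k = index.params.k
        self.cache = CandidateCache() if config.use_cache else None

    # ---- stage 1: sequential (cache is order-dependent) ----

    def end_candidates(self, seq: str) -> _EndState:
        mins = extract_minimizers(seq, self.index.params)
        if len(mins) == 0:
            return _EndState(seq, None, [])
        cands = None
        if self.cache is not None:
            vec = MinimizerVector.from_minimizers(mins, len(seq), self.k)
            cands = self.cache.lookup(vec)
            if cands is None:
                anchors = query_index(self.index, mins)
                cands = generate_candidates(anchors, len(seq), self.k, self.config.candidate)
                self.cache.update(vec, cands)
        else:
            anchors = query_index(self.index, mins)
            cands = generate_candidates(anchors, len(seq), self.k, self.config.candidate)
        return _EndState(seq, mins, cands)

    def _supplement(self, end: _EndState, mate: _EndState) -> list:
        mate_best = best_candidate(mate.candidates)
        if mate_best is None or end.minimizers is None:
            return []
        return supplement_candidates(
            self.index, end.minimizers, len(end.seq), mate_best, self.config.candidate
        )

    @staticmethod
    def _merge_cands(primary: Sequence[Candidate], extra: Sequence[Candidate]) -> list:
        seen = {(c.position, c.strand): c for c in primary}
        for c in extra:
            key = (c.position, c.strand)
            if key not in seen or c.multiplicity > seen[key].multiplicity:
                seen[key] = c
        return list(seen.values())

    def stage1(self, pair: ReadPair) -> _PairState:
        cfg = self.config
        if cfg.trim_adapters and pair.r2 is not None:
            pair = trim_adapters(pair, cfg.trim)
        e1 = self.end_candidates(pair.r1.seq)
        e2 = self.end_candidates(pair.r2.seq) if pair.r2 is not None else None
        if e2 is not None and cfg.preset != "hic":
            if cfg.always_supplement:
                e1.candidates = self._merge_cands(e1.candidates, self._supplement(e1, e2))
                e2.candidates = self._merge_cands(e2.candidates, self._supplement(e2, e1))
            else:
                if not e1.candidates and e2.candidates:
                    e1.candidates = self._supplement(e1, e2)
                if not e2.candidates and e1.candidates:
                    e2.candidates = self._supplement(e2, e1)
        return _PairState(pair.r1.name, e1, e2, pair.r1.barcode_seq)

    # ---- stage 2: pure, thread-parallel ----

    def map_single(self, st: _PairState) -> Optional[MappingRecord]:
        out = verify_candidates(st.e1.seq, st.e1.candidates, self.genome, self.config.verify)
        if out.best is None:
            return None
        mapq = compute_mapq(out.best, out.second_best_distance, out.num_best)
        chrom, ls = self.genome.to_local(out.best.start)
        return MappingRecord(
            chrom, ls, ls + (out.best.end - out.best.start), out.best.strand,
            mapq, out.best.edit_distance, barcode=st.barcode, name=st.name,
        )

    def map_fragment(self, st: _PairState) -> Optional[MappingRecord]:
        cfg = self.config
        e1, e2 = st.e1, st.e2
        assert e2 is not None
        pairs = pair_filter(
            e1.candidates, e2.candidates, len(e1.seq), len(e2.seq),
            cfg.candidate.fragment_min, cfg.candidate.fragment_max,
        )
        if not pairs:
            return None
        c1set = list(dict.fromkeys(a for a, _ in pairs))
        c2set = list(dict.fromkeys(b for _, b in pairs))
        s1 = {cs.candidate: cs for cs in score_candidates(e1.seq, c1set, self.genome, cfg.verify)}
        s2 = {cs.candidate: cs for cs in score_candidates(e2.seq, c2set, self.genome, cfg.verify)}
        combos = [
            (s1[a].edit_distance + s2[b].edit_distance, a, b)
            for a, b in pairs
            if a in s1 and b in s2
        ]
        if not combos:
            return None
        combos.sort(key=lambda c: (c[0], c[1].position, c[2].position, c[1].strand))
        best_total, a, b = combos[0]
        num_best = sum(1 for c in combos if c[0] == best_total)
        second = combos[1][0] if len(combos) > 1 else None
        mapq = mapq_from_distances(best_total, second, num_best)
        r1 = finish_alignment(self.genome, s1[a])
        r2 = finish_alignment(self.genome, s2[b])
        ci1 = self.genome.chrom_index(r1.start)
        if ci1 != self.genome.chrom_index(r2.start):
            return None
        start = min(r1.start, r2.start)
        end = max(r1.end, r2.end)
        chrom, ls = self.genome.to_local(start)
        le = ls + (end - start)
        if cfg.tn5_shift and le - 5 > ls + 4:
            ls, le = ls + 4, le - 5
        return MappingRecord(
            chrom, ls, le, r1.strand, mapq, best_total,
            barcode=st.barcode, name=st.name,
        )

    def _map_hic_end(self, end: _EndState):
        cfg = self.config
        out = verify_candidates(end.seq, end.candidates, self.genome, cfg.verify)
        if out.best is not None:
            return out.best, compute_mapq(out.best, out.second_best_distance, out.num_best)
        if not end.candidates:
            return None, 0
        res = split_map(end.seq, end.candidates, self.genome, cfg.verify)
        if res is None:
            return None, 0
        # Split mappings have no runner-up statistics; confidence scales
        # with the split score (mapped length minus edit distance).
        return res, max(0, min(60, res.score))

    def map_contact(self, st: _PairState) -> Optional[ContactRecord]:
        assert st.e2 is not None
        a1, q1 = self._map_hic_end(st.e1)
        a2, q2 = self._map_hic_end(st.e2)
        if a1 is None or a2 is None:
            return None
        chrom1, ls1 = self.genome.to_local(a1.start)
        chrom2, ls2 = self.genome.to_local(a2.start)
        pos1 = ls1 if a1.strand == "+" else ls1 + (a1.end - a1.start) - 1
        pos2 = ls2 if a2.strand == "+" else ls2 + (a2.end - a2.start) - 1
        rec = ContactRecord(
            st.name, chrom1, pos1, a1.strand, chrom2, pos2, a2.strand,
            mapq=min(q1, q2),
        )
        return orient_contact(rec, self.genome.chrom_rank)

    def map_one(self, st: _PairState):
        if self.config.preset == "hic":
            return self.map_contact(st)
        if st.e2 is None:
            return self.map_single(st)
        return self.map_fragment(st)


def _batches(iterable, size: int):
    batch = []
    for item in iterable:
        batch.append(item)
        if len(batch) >= size:
            yield batch
            batch = []
    if batch:
        yield batch


def run_pipeline(
    index: MinimizerIndex,
    config: PipelineConfig,
    r1_path: PathLike,
    r2_path: Optional[PathLike] = None,
    barcode_path: Optional[PathLike] = None,
    out_prefix: PathLike = "chromalign_out",
    keep_per_read: bool = False,
) -> RunReport:
    """Map reads end to end and write analysis-ready output.

    Returns a run report with stage counts (conserved: mapped + unmapped +
    rejected = input), cache statistics, and the duplicate rate. Output is
    deterministic for a fixed config regardless of ``config.threads``.
    """
    cfg = config
    if cfg.preset == "hic" and r2_path is None:
        raise ValueError("the hic preset requires paired reads")
    whitelist = None
    if cfg.barcode_whitelist is not None:
        if barcode_path is None:
            raise ValueError("a barcode whitelist requires a barcode FASTQ")
        from .io_formats import _fastq_records

        whitelist = build_whitelist(
            cfg.barcode_whitelist, (seq for _t, seq, _q in _fastq_records(barcode_path))
        )
    mapper = _Mapper(index, cfg)
    report = RunReport(preset=cfg.preset, paired=r2_path is not None, dedup_level=cfg.dedup_level)
    if keep_per_read:
        report.per_read = []

    results = []
    executor = ThreadPoolExecutor(cfg.threads) if cfg.threads > 1 else None
    try:
        stream = stream_read_pairs(r1_path, r2_path, barcode_path)
        for batch in _batches(stream, cfg.batch_size):
            states = []
            for pair in batch:
                report.total += 1
                if whitelist is not None:
                    bc = pair.r1.barcode_seq
                    corrected = (
                        correct_barcode(bc, pair.r1.barcode_quals or "I" * len(bc),
                                        whitelist, cfg.bc_threshold)
                        if bc is not None
                        else None
                    )
                    if corrected is None:
                        report.barcode_rejected += 1
                        if keep_per_read:
                            report.per_read.append((pair.r1.name, None))
                        continue
                    pair.r1.barcode_seq = corrected
                states.append(mapper.stage1(pair))
            if executor is not None:
                mapped = list(executor.map(mapper.map_one, states))
            else:
                mapped = [mapper.map_one(s) for s in states]
            for st, rec in zip(states, mapped):
                if rec is None:
                    report.unmapped += 1
                else:
                    report.mapped += 1
                    results.append(rec)
                if keep_per_read:
                    report.per_read.append((st.name, rec))
    finally:
        if executor is not None:
            executor.shutdown()

    if mapper.cache is not None:
        report.cache_hits = mapper.cache.hits
        report.cache_misses = mapper.cache.misses
        report.cache_updates = mapper.cache.updates

    out_prefix = str(out_prefix)
    rank = mapper.genome.chrom_rank
    report.records_before_dedup = len(results)
    if cfg.preset == "hic":
        deduped = remove_duplicate_contacts(results, rank)
        out_path = out_prefix + ".pairs"
        write_pairs(deduped, out_path, index.chromsizes)
    else:
        if cfg.low_memory:
            deduped = external_sort_dedup(
                results, cfg.dedup_level, rank, chunk_size=cfg.dedup_chunk_size
            ).records
        else:
            deduped = remove_duplicates(results, cfg.dedup_level, rank)
        if r2_path is None:
            out_path = out_prefix + ".bed"
            write_bed(deduped, out_path, rank)
        else:
            out_path = out_prefix + ".bedpe"
            write_bedpe(deduped, out_path, rank)
    report.records_after_dedup = len(deduped)
    if report.records_before_dedup:
        report.duplicate_rate = 1.0 - report.records_after_dedup / report.records_before_dedup
    report.outputs["mappings"] = out_path

    logger.info(
        "preset=%s total=%d mapped=%d unmapped=%d bc_rejected=%d "
        "cache_hits=%d cache_misses=%d cache_updates=%d dup_rate=%.4f",
        cfg.preset, report.total, report.mapped, report.unmapped,
        report.barcode_rejected, report.cache_hits, report.cache_misses,
        report.cache_updates, report.duplicate_rate,
    )
    return report


def write_report(report: RunReport, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
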