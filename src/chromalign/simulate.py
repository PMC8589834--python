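"""Synthetic genomes and reads with embedded truth, and mapping accuracy.

The generator stands in for a real reference at desk scale: an i.i.d.
nucleotide background with exact duplicated blocks planted to a requested
repeat fraction, and paired reads drawn from a normal fragment-length
distribution with per-base substitution errors. Ground truth (chromosome,
fragment interval, R1 strand) is encoded in the read names, so accuracy
can be scored exactly the way mapeval-style tools do: a mapping at
sufficient MAPQ is correct iff it lands on the truth chromosome and
strand and its interval overlaps the truth interval.

Adapter read-through pairs (fragment shorter than the read) and cell
barcodes drawn from a whitelist with injected substitution errors exercise
the preprocessing stages. A ``hotspots`` option concentrates fragments on
a fixed set of start positions, emulating the enrichment of chromatin
profiles that makes the candidate cache effective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .io_formats import Genome, GenomeSequence, MappingRecord, SequencedRead, revcomp

PathLike = Union[str, Path]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# adapter fill used beyond short fragments (Tn5/Nextera-like mosaic ends)
ADAPTER_R1 = "CTGTCTCTTATACACATCTCCGAGCCCACGAGAC"
ADAPTER_R2 = "CTGTCTCTTATACACATCTGACGCTGCCGACGA"

_SEP = "!"


@dataclass(slots=True)
class SimulatedGenome:
    genome: Genome
    repeats: list[tuple[str, int, int]] = field(default_factory=list)  # planted copies


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def generate_genome(
    length: int,
    n_chroms: int = 1,
    repeat_fraction: float = 0.0,
    repeat_unit_length: int = 500,
    seed: int = 0,
) -> SimulatedGenome:
    """An i.i.d. random genome with planted exact duplications.

    ``repeat_fraction`` of the genome is overwritten with copies of blocks
    sampled elsewhere on the same chromosome, giving exact two-copy (or
    more) repeats of ``repeat_unit_length``. Deterministic given the seed.
    """
    if length < repeat_unit_length and repeat_fraction > 0:
        raise ValueError("genome shorter than the repeat unit")
    rng = np.random.default_rng(seed)
    per = length // n_chroms
    seqs = []
    repeats: list[tuple[str, int, int]] = []
    for ci in range(n_chroms):
        n = per if ci < n_chroms - 1 else length - per * (n_chroms - 1)
        name = f"chr{ci + 1}"
        arr = np.array(list(_random_seq(rng, n).encode("ascii")), dtype=np.uint8)
        target = int(repeat_fraction * n)
        planted = 0
        guard = 0
        used: list[tuple[int, int]] = []
        while planted < target and guard < 50_000:
            guard += 1
            if n < 2 * repeat_unit_length + 2:
                break
            src = int(rng.integers(0, n - repeat_unit_length))
            dst = int(rng.integers(0, n - repeat_unit_length))
            if abs(dst - src) < repeat_unit_length:
                continue
            # planted intervals must stay disjoint from each other, or a
            # later copy would overwrite an earlier one and break exactness
            new = [(src, src + repeat_unit_length), (dst, dst + repeat_unit_length)]
            if any(a < ue and ua < b for a, b in new for ua, ue in used):
                continue
            arr[dst : dst + repeat_unit_length] = arr[src : src + repeat_unit_length]
            used.extend(new)
            repeats.append((name, src, src + repeat_unit_length))
            repeats.append((name, dst, dst + repeat_unit_length))
            planted += repeat_unit_length
        seqs.append(GenomeSequence(name, arr.tobytes().decode("ascii")))
    return SimulatedGenome(Genome(seqs), repeats)


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        cur = arr[i]
        choices = _BASES[_BASES != cur]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def _qual_string(error_rate: float, n: int) -> str:
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * np.log10(error_rate))))
    return chr(q + 33) * n


def truth_name(idx: int, chrom: str, start: int, end: int, strand: str,
               barcode: Optional[str] = None) -> str:
    name = _SEP.join([f"sim{idx}", chrom, str(start), str(end), strand])
    if barcode is not None:
        name += _SEP + barcode
    return name


def parse_truth(name: str) -> tuple[str, int, int, str]:
    """Recover (chrom, start, end, strand) from a simulated read name."""
    parts = name.split(_SEP)
    if len(parts) < 5:
        raise ValueError(f"read name {name!r} carries no simulation truth")
    return parts[1], int(parts[2]), int(parts[3]), parts[4]


@dataclass(slots=True)
class SimulatedReads:
    r1: list[SequencedRead]
    r2: list[SequencedRead]
    barcodes: list[SequencedRead]


def simulate_reads(
    sim: SimulatedGenome,
    n_pairs: int,
    read_len: int = 100,
    error_rate: float = 0.001,
    fragment_mean: float = 250.0,
    fragment_sd: float = 50.0,
    adapter_readthrough_fraction: float = 0.0,
    barcode_whitelist: Optional[Sequence[str]] = None,
    barcode_error_rate: float = 0.0,
    hotspots: Optional[int] = None,
    seed: int = 0,
) -> SimulatedReads:
    """Paired reads with truth in the names.

    Fragments are placed uniformly (or, with ``hotspots``, drawn from that
    many fixed start positions to emulate peak enrichment); lengths follow
    a normal distribution clipped to at least the read length, except for
    read-through pairs whose fragment is shorter than the read and whose
    3' ends run into adapter sequence. Substitution errors occur per base
    at ``error_rate``; qualities encode that error probability. With
    probability 1/2 the mates swap roles so R1 sits on either strand.
    """
    genome = sim.genome
    rng = np.random.default_rng(seed)
    weights = genome.lengths / genome.lengths.sum()
    hotspot_pool = None
    if hotspots is not None:
        ci = rng.integers(0, len(genome.names), size=hotspots)
        hotspot_pool = [
            (int(c), int(rng.integers(0, max(1, genome.lengths[c] - 3 * read_len))))
            for c in ci
        ]
    r1s, r2s, bcs = [], [], []
    for i in range(n_pairs):
        readthrough = rng.random() < adapter_readthrough_fraction
        if readthrough:
            frag_len = int(rng.integers(max(30, read_len // 3), read_len))
        else:
            frag_len = int(np.clip(rng.normal(fragment_mean, fragment_sd), read_len, None))
        if hotspot_pool is not None:
            ci, start = hotspot_pool[int(rng.integers(0, len(hotspot_pool)))]
        else:
            ci = int(rng.choice(len(genome.names), p=weights))
            start = int(rng.integers(0, max(1, genome.lengths[ci] - frag_len)))
        chrom = genome.names[ci]
        end = min(start + frag_len, int(genome.lengths[ci]))
        frag = genome.sequences[ci].seq[start:end]
        fwd = frag[:read_len]
        rev = revcomp(frag)[:read_len]
        if readthrough:
            fwd = (frag + ADAPTER_R1)[:read_len]
            rev = (revcomp(frag) + ADAPTER_R2)[:read_len]
        flip = rng.random() < 0.5
        s1, s2 = (rev, fwd) if flip else (fwd, rev)
        strand1 = "-" if flip else "+"
        barcode = None
        bc_obs = None
        if barcode_whitelist is not None:
            barcode = barcode_whitelist[int(rng.integers(0, len(barcode_whitelist)))]
            bc_obs = _apply_errors(rng, barcode, barcode_error_rate)
        name = truth_name(i, chrom, start, end, strand1, barcode)
        s1 = _apply_errors(rng, s1, error_rate)
        s2 = _apply_errors(rng, s2, error_rate)
        r1s.append(SequencedRead(name, s1, _qual_string(error_rate, len(s1))))
        r2s.append(SequencedRead(name, s2, _qual_string(error_rate, len(s2))))
        if bc_obs is not None:
            bcs.append(SequencedRead(name, bc_obs, _qual_string(0.001, len(bc_obs))))
    return SimulatedReads(r1s, r2s, bcs)


# ---------------------------------------------------------------------------
# mapeval-style accuracy
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class MapevalResult:
    n_mapped: int
    n_correct: int
    accuracy: float
    curve: list[tuple[int, int, int, float]]  # (cutoff, n_mapped, n_correct, acc)


def _is_correct(rec: MappingRecord, truth: tuple[str, int, int, str]) -> bool:
    chrom, start, end, strand = truth
    return (
        rec.chrom == chrom
        and rec.strand == strand
        and rec.start < end
        and rec.end > start
    )


def mapeval_accuracy(
    mappings: Sequence[tuple[str, Optional[MappingRecord]]],
    mapq_cutoff: int = 30,
    check_strand: bool = True,
) -> MapevalResult:
    """Fraction of sufficiently confident mappings that hit their truth.

    A mapping with MAPQ >= cutoff is correct iff it lies on the truth
    chromosome (and strand, unless ``check_strand`` is off) and overlaps
    the truth interval. Also returns the whole cutoff curve; raising the
    cutoff can only shrink n_mapped.
    """
    scored = []
    for name, rec in mappings:
        if rec is None:
            continue
        truth = parse_truth(name)
        if not check_strand:
            ok = rec.chrom == truth[0] and rec.start < truth[2] and rec.end > truth[1]
        else:
            ok = _is_correct(rec, truth)
        scored.append((rec.mapq, ok))
    curve = []
    result = None
    for cutoff in range(0, 61, 10):
        n_mapped = sum(1 for q, _ in scored if q >= cutoff)
        n_correct = sum(1 for q, ok in scored if q >= cutoff and ok)
        acc = n_correct / n_mapped if n_mapped else 0.0
        curve.append((cutoff, n_mapped, n_correct, acc))
        if cutoff == mapq_cutoff:
            result = (n_mapped, n_correct, acc)
    if result is None:
        n_mapped = sum(1 for q, _ in scored if q >= mapq_cutoff)
        n_correct = sum(1 for q, ok in scored if q >= mapq_cutoff and ok)
        result = (n_mapped, n_correct, n_correct / n_mapped if n_mapped else 0.0)
    return MapevalResult(result[0], result[1], result[2], curve)


def write_mapeval_tsv(result: MapevalResult, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("cutoff\tn_mapped\tn_correct\taccuracy\n")
        for cutoff, n_mapped, n_correct, acc in result.curve:
            fh.write(f"{cutoff}\t{n_mapped}\t{n_correct}\t{acc:.6f}\n")
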