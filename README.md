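# chromalign

Fast alignment and preprocessing of chromatin profiles — ChIP-seq,
(sc)ATAC-seq, and Hi-C — in one pass. Instead of producing base-level
alignments for variant calling, chromatin workflows only need accurate
read *coordinates*; chromalign exploits that to fuse mapping, adapter
trimming, cell-barcode correction, and duplicate removal into a single
tool that writes analysis-ready BED/BEDPE/4DN-pairs output directly.

## Method

**Seeding.** Double-strand minimizers — the k-mer minimizing an
invertible hash over each window of `w` consecutive k-mers (defaults
`k=17`, `w=7`), canonicalized over both strands — are extracted from the
reference and indexed in a hash table mapping each key to its sorted
occurrence list. Keys occurring more than 500 times on the reference are
masked at query time.

**Candidate generation.** Each exact minimizer hit between read and
reference is an *anchor* `(x, y)` (`x` = start on the reference, `y` =
start on the read), estimating a candidate mapping start `x − y` (on the
reverse strand, `x − (L − k − y)`). All anchor estimates are sorted and
merged in one linear scan: positions within the edit-distance budget `t`
(default 8) collapse into a candidate carrying its supporting-anchor
multiplicity. Paired ends are filtered by orientation and fragment
length; an end left without candidates by the occurrence mask is rescued
by binary-searching the occurrence lists inside the window implied by its
mate's best candidate.

**Candidate cache.** Chromatin reads pile up in peaks, so identical
minimizer vectors recur. A fixed table of `N = 2,000,003` entries keyed
by `h(m) = (m1 + mM) mod N` caches the candidates of frequent vectors;
each entry holds a count array of size `N′ = 103` addressed by
`f(m) = (m1 ⊕ mM) mod N′` with a Boyer–Moore majority tracker per cell,
and the stored entry is replaced only when a vector's cell exceeds 20% of
the entry total *and* dominates its cell. Both hash functions commute, so
a read and its reverse complement share one entry. Cached candidates are
re-based onto the querying read's frame, making the cache a pure
accelerator: output is bit-identical with the cache on or off.

**Verification.** Every candidate is verified with a banded Myers
bit-parallel edit-distance scan over a reference window of width
`L + 2t`; a modified traceback (a reversed scan) recovers exact start/end
coordinates. MAPQ (0–60) falls to 0 on ties and scales with the margin
between best and runner-up distance. For Hi-C, reads failing the edit
threshold fall through to split mapping: the longest prefix-anchored
mapping is kept if long enough (score = mapped length − edit distance),
otherwise the first 20 bp are excluded, the remainder remapped, and the
mapping extended backward by maximal exact matching.

**Preprocessing/postprocessing.** Adapter read-through in (sc)ATAC pairs
is detected by overlap between R1 and revcomp(R2) using two `l_ovp/2`
seeds (any true overlap ≥ `l_ovp` with ≤ 1 mismatch is found, by
pigeonhole) and trimmed to the fragment. Off-whitelist cell barcodes are
corrected to the one-Hamming whitelisted neighbor whose posterior —
abundance prior × mismatch-quality likelihood — reaches 90%. Duplicates
are removed at bulk or cell level, in memory or via an external sort with
byte-identical output.

## Worked example

```sh
chromalign index -r ref.fa -o ref.idx
# indexed 1 sequences, 25008 minimizer keys
chromalign map --preset chip -x ref.idx -1 r1.fq -2 r2.fq -o out
# 500/500 mapped, 500 records after deduplication -> out.bedpe
head -3 out.bedpe
# chr1    2       232     1       +
# chr1    24      230     1       +
# chr1    53      304     1       +
```

Each fragment line gives chromosome, 0-based half-open fragment
coordinates (outermost ends of the pair), the number of duplicates
collapsed into the record, and the strand of R1; with a barcode whitelist
(`--preset atac --barcode-whitelist wl.txt -b barcodes.fq`) a corrected
cell-barcode column is inserted before the count. `--preset hic` writes
upper-triangle-sorted 4DN pairs instead. The library API mirrors the CLI
(`chromalign.build_index`, `chromalign.run_pipeline`), and
`chromalign.simulate` generates seeded synthetic genomes and reads with
ground truth encoded in read names for accuracy evaluation.

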