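# Methods

This note documents the models, conventions, and numerical choices behind
chromalign, and what the synthetic benchmarks do and do not demonstrate.

## Minimizer sketch and index

A k-mer is 2-bit encoded (A=0, C=1, G=2, T=3; `k ≤ 28` keeps the encoding
in one machine word) and hashed with a Murmur-style invertible finalizer
masked to `2k` bits. Because the hash is a bijection, two k-mers have
equal keys iff they are equal; the canonical key of a position is the
smaller of the forward and reverse-complement hashes, and the winning
strand is recorded. A k-mer whose two hashes are equal (only possible for
even `k`, where a k-mer can be its own reverse complement) is skipped.
Within each window of `w` consecutive valid k-mers, *every* position
achieving the minimum key is reported — keeping all ties preserves
double-strand sensitivity. Any k-mer containing N is invalid and breaks
windows, so assembly gaps seed nothing.

Defaults `k=17, w=7` suit short chromatin reads (~50–150 bp): dense
enough that a 50 bp read retains several minimizers, sparse enough to
keep the index small. The occurrence mask (`max_occ=500`, strict `>`) is
applied at query time, never at build time, so mate rescue can still
reach masked occurrences. The index file is self-contained (parameters,
chromosome table, genome digest, occurrence arrays, and the reference
sequence itself) and serializes deterministically: two builds of the same
FASTA are byte-identical.

## Candidate generation, rescue, and the cache

Candidates are merged from sorted per-anchor estimates in one linear
scan; the merge radius equals the edit-distance budget so small indels
cannot split a locus into two candidates. The merged representative is
the smallest member position — verification relocates the exact start
anyway, so the representative only needs to be deterministic and within
the band. `min_support` defaults to 1 (no anchor evidence is discarded);
the paired fragment-length window defaults to [30, 2000] bp, spanning
nucleosome-free ATAC fragments through long ChIP fragments.

Mate rescue is attempted only for an end with zero surviving candidates
(a flag forces it always): for each of its minimizers, the sorted
occurrence list is binary-searched within mate ± max fragment length,
ignoring the occurrence mask, and candidate generation reruns on the
restricted anchors.

The cache key is the full minimizer vector (keys plus inter-minimizer
offsets), canonicalized against its reversal so both strands of a read
retrieve one entry. Stored candidates travel with the contributing read's
frame offsets (first-minimizer offset and 3'-tail offset) and are shifted
into the querying read's frame on a hit; this is what lets nearby reads
that share a vector share cached work without changing any result. The
admission rule (cell count > 20% of entry total, and the vector is the
cell's Boyer–Moore majority occupant) keeps background vectors from
evicting genuinely frequent ones. The majority vote is O(1) per cell and
detects any occupant exceeding half the cell's updates. Because the
stage is order-dependent by construction, the pipeline runs it strictly
in input order; transparency (cache on ≡ cache off) is asserted by test
and by the acceptance script.

## Verification, MAPQ, and split mapping

Verification computes the minimum edit distance between the full read and
the reference window `candidate ± t` (width `L + 2t`) with Myers'
bit-parallel approximate-matching recurrence; the window width bounds the
diagonal band and distances above `t` are rejected. Bit vectors live in
Python arbitrary-precision integers, so reads longer than 64 bp use the
same code path as short ones (verified against a plain DP oracle at
lengths 20–300). The alignment end is the smallest window offset
achieving the minimum; the start comes from rerunning the scan on the
reversed strings, taking the shortest span on ties. Windows are clamped
to chromosome bounds so alignments never cross a chromosome junction in
the concatenated coordinate space. `t=8` by default (≈8% of a 100 bp
read) accommodates 0.1%-error data plus small variants.

MAPQ is this package's deterministic convention, not a probability
model: ties at the best distance give 0, a sole candidate with no
runner-up gives 60, otherwise `min(60, 20·(d₂ − d₁))`; it is monotone in
the runner-up distance. Ties are reported at the smallest reference
coordinate (with MAPQ 0 marking the ambiguity).

Split mapping (Hi-C preset only) engages when full-length verification
fails. Per candidate, a row-vectorized semi-global DP finds the longest
read prefix placeable within the band (row minima are non-decreasing in
prefix length, so the scan stops at first violation). A mapping shorter
than `min_split_length` (default 30 bp — short enough to keep genuine
junction fragments, long enough to avoid spurious hits) triggers a second
round with the first 20 bp excluded, followed by backward maximal exact
extension into the excluded bases. The reported score is mapped length
minus edit distance; for split mappings, which have no runner-up
statistics, MAPQ is the score clamped to [0, 60]. Reverse-strand split
mapping reverse-complements the window so "read prefix" means the same
thing on both strands. Pair constraints (fragment length, strandness) are
ignored in split mode.

## Trimming and barcode correction

Read-through trimming compares R1 against revcomp(R2): a fragment shorter
than the read appears as a prefix of one and a suffix of the other. Two
seeds of length `l_ovp/2` at R1 offsets 0 and `l_ovp/2` are located
exactly in revcomp(R2); each hit implies an overlap length, verified at
≤ 1 Hamming mismatch. Pigeonhole gives the guarantee: one mismatch can
disrupt at most one seed. Among valid overlaps the longest wins
(deterministic; protects against chance short overlaps). `l_ovp` defaults
to 25 (seeds of 12 bp are long enough that random hits essentially never
verify).

Barcode correction is whitelist-driven: abundances are exact-match counts
over the observed barcode reads plus a pseudo-count of 1 (so rare but
real barcodes keep a nonzero prior). For an off-list barcode, every
one-substitution neighbor is enumerated by XOR masking on the 2-bit
encoding; for whitelisted neighbors the posterior is
`abundance × (10^(−q/10))/3` normalized over candidates, where `q` is the
observed quality at the mismatched base. The correction is accepted iff
the maximum posterior is ≥ 0.9. A single ambiguous (N) base is treated as
the mismatch position; two or more reject the barcode. Only
substitutions are considered — correction is defined within Hamming
distance 1.

## Deduplication

Fragment identity is both endpoints plus strand (and the corrected
barcode at cell level, the default whenever barcodes are present); Hi-C
contacts are keyed on both ends jointly. Records sort by chromosome in
reference order, then start, end, strand, barcode, with MAPQ/edit/name as
final tie-breakers so the in-memory and external-sort paths pick the same
representative; the external path (sorted chunk spills + k-way merge) is
byte-identical to the in-memory path by test.

## Pipeline determinism

Stage 1 (trimming, minimizers, cache, candidates, rescue) runs in input
order; stage 2 (verification, split mapping) is a pure function fanned
out over a thread pool with order-preserving collection. Outputs are
therefore byte-identical across thread counts and across runs. Barcode
correction overlapping with I/O is treated as an implementation detail
with no observable effect. Stage counts in the run report are conserved:
mapped + unmapped + barcode-rejected = input reads.

## Synthetic data: what it shows and what it does not

The generator produces an i.i.d. uniform background with planted,
mutually disjoint exact duplications (disjointness keeps every planted
copy a true exact repeat), normal fragment lengths, substitution-only
errors with matching quality strings, optional read-through pairs with
Tn5-style adapter fill, and barcodes drawn uniformly from a whitelist
with injected substitutions. A `hotspots` option concentrates fragments
on fixed start positions to emulate peak enrichment. Truth (chromosome,
fragment interval, R1 strand) rides in the read names; accuracy follows
mapeval semantics — same chromosome and strand, overlapping interval, at
a MAPQ cutoff.

Benchmarks run at desk scale: a 1 Mb genome with 10% repeat content,
10k 100 bp pairs at 0.1% error for accuracy; 100k single-end reads from
200 hotspots for cache transparency; 5k pairs for determinism. These
sizes exercise every code path while keeping the whole suite in minutes.
What passing shows: the algorithms are mutually consistent, match
independent oracles, and recover planted truth nearly perfectly under
this error model. What it does not show: performance on real genomes
(repeat families are far more complex than exact copies), indel-rich or
quality-skewed data (the error model is substitution-only by default),
or Hi-C libraries beyond simple two-locus chimeras.

## Known limitations

- No affine-gap scoring or CIGAR output; coordinates and edit distance
  only (by design — downstream chromatin analyses need coordinates).
- MAPQ is a convention, comparable within this tool but not calibrated
  to error probabilities.
- The candidate cache persists only within a run.
- Occurrence-mask counts combine both strands of the reference.
- Split mapping reports the 5'-side mapping of a chimeric read; the
  3'-side locus is recovered only through the mate, as in standard Hi-C
  pair processing.
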