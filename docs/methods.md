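# Methods notes

## Chip model and CID matching

A chip is a `width × height` lattice of capture spots (bin1), each carrying
a distinct 25-base CID; the mask is the injective CID → (x, y) table.
Coordinates are 0-based with x the column and y the row (the convention is
pinned here because mask vendors do not publish one). The mask format is a
versioned TSV (`#chip=… width=… height=… cid_length=…` header, then
`CID<TAB>x<TAB>y`), chosen for transparency and diffability at desk scale;
binary vendor formats are out of scope.

Restoration tries an exact hash lookup first (an exact hit is strictly more
probable than any distance-1 alternative), then the 3 × 25 single-base
substitution variants. Exactly one variant hit restores the read as
`corrected`; hits at ≥ 2 distinct coordinates are discarded as `ambiguous`
(the conservative choice — no quality-aware rescue is attempted); zero hits
leave it `unmatched`. Distance is capped at one substitution; indels are
not considered. A CID containing N can never match exactly, but an N
position participates in variant substitution, so a single N is
correctable. The mismatch position is recorded for diagnostics only.

### Partitioning

Masks and reads can be partitioned by the first `p` bases of the CID
(`4^p` parts, A=0 C=1 G=2 T=3) or by the big-endian 2-bit encoding of the
full CID modulo `n` (the encoding and the full-CID modulo are pinned here;
any fixed bijection would do, one must be chosen for reproducibility).
CIDs with non-ACGT symbols fall back to partition 0 — they cannot match
exactly anywhere, and variant lookups are routed independently. During
matching, each substitution variant is looked up in the partition *that
variant* encodes to, so a read whose single error falls inside the
partitioning prefix is still recovered and partitioned matching is exactly
equivalent to whole-mask matching. This equivalence is asserted
byte-for-byte on end-to-end outputs for 1, 4 and 16 partitions.

## Read QC

The filters run in a fixed order and the first failure is reported: MID
contains N; MID is poly-A; any MID base below a per-base Phred floor
(default 10); then a trailing cDNA A-run of ≥ 10 bases is trimmed and the
read fails if fewer than 25 bases remain. Choices pinned as this package's
dialect: the quality rule is a per-base minimum (not a mean), and cDNA
poly-A is trimmed rather than discarded — poly-A tails are expected
biology, and discarding every tailed read would be far harsher than any
published retention figure suggests. All thresholds are parameters.

## Annotation

CIGAR semantics: M/=/X extend the current reference block, N and D close
it (both advance the reference), I and S consume read only, H and P
neither; read length is the sum of read-consuming operations. Per gene,
each transcript is scored separately: `exoncnt` is the block overlap with
that transcript's exons, `introncnt` the overlap with the gene span minus
those exons (intron regions are transcript-specific); the transcript
maximizing (exoncnt, then introncnt) represents the gene — mixing
transcripts per block would be biologically incoherent. Labels follow the
50 %-of-read-length rule. Gene choice: best label first, then the largest
total overlap, ties resolved by smallest (start, end, gene_id) —
deterministic by design, preferring testability. "Uniquely mapped" means
primary, non-supplementary, and MAPQ = 255 (STAR-style unique) or ≥ 20
(configurable). Strand never influences the label; it only sets the
antisense flag. Tallies count antisense reads under their region label
*and* under Antisense, with transcriptome = exonic + intronic; the
expression matrix later excludes antisense reads.

## MID correction

Within each (spot, gene) group: if the group has fewer than
`min_mid_types` (default 5) distinct MIDs it is left untouched. Otherwise
MIDs are ranked by descending count, ties by descending lexicographic
order (this tie rule is pinned; it makes the procedure deterministic), and
traversed from the lowest rank upward; each MID scans ranks 0..i−1 in
order and transfers its current count to the first MID within the Hamming
tolerance (default 1). Ranks are fixed by the original sort; transfers
move counts, not ranks. Defaults are 5 / 1 / 10 (gate / tolerance / MID
length). Counts are conserved exactly and no MID is created.

A merge target can itself merge later in the traversal (it sits at a
higher rank, processed afterwards), so the stored old → new mapping can
chain; per-read resolution follows chains to the surviving MID (each hop
moves strictly up the rank order, so resolution terminates), which makes
replaying the mapping over raw reads reproduce the corrected counts
exactly.

Two consequences of the published defaults worth knowing: groups sparser
than the 5-type gate are never corrected, so at bin1 resolution most
singleton spots keep their sequencing-error MIDs; and tolerance 1 cannot
merge a doubly-substituted MID. The parameter-recovery test therefore uses
groups with a fixed 6 molecules (gate always passes); its ≥ 95 % recovery
bound is set by the residual double-substitution probability
(≈ 30 reads × 0.001 ≈ 3 %).

## Expression matrix

Matrix value = number of distinct corrected MIDs per (x, y, gene), from
EXONIC/INTRONIC sense-strand reads only. Binning uses 0-based floor
division and emits bin indices (bin_size recorded in metadata); summing is
the only aggregation and totals are invariant under bin size. Output
formats: a GEM TSV (`geneID  x  y  MIDCount` with a metadata header) and
an HDF5 container (`/expression/{gene,x,y,count}`, `/metadata`); both
round-trip losslessly. Records are canonically sorted by (x, y, gene), so
identical runs produce byte-identical files regardless of partition count
or batch size.

## Tissue segmentation

The heatmap (per-bin total counts) is segmented by: log1p transform →
Gaussian smoothing (σ = 1 bin) → 8-bit rescale → Otsu threshold (fixed
threshold optional) → morphological closing (r = 2) then opening (r = 1)
→ removal of components below 0.1 % of the image area → hole filling →
contour tracing (image padded so border-touching tissue closes). The
operator chain and defaults are this package's dialect — classical
grayscale segmentation admits many; all knobs are in
`SegmentationParams`. Degenerate inputs are defined, not errors: an
all-zero image gives an empty mask, a constant positive image a full-frame
mask. A learned segmenter for microscope images is deliberately out of
scope.

## Saturation

From tissue-region (x, y, gene, MID, count) tuples, a fraction (default
5 %) of occupied bin200 cells is sampled (ceiling, so never empty), the
per-read list is expanded and shuffled once, and each fraction takes a
prefix — prefixes are nested, so totals strictly increase and distinct
counts never decrease. Saturation = 1 − unique/total with uniqueness on
(bin1 x, y, gene, MID); under that key the bin1 and bin200 saturation
columns coincide, and both are reported (an alternative reading that
deduplicates at bin200 resolution is available behind
`bin200_resolution_keys`). Median genes per bin is taken over occupied
bins only.

## Synthetic data

The generator emulates: a chip with one random CID per spot (for chips
≤ 5,000 spots, CIDs are resampled until all pairwise Hamming distances are
≥ 3, making single-error correction unambiguous by construction);
non-overlapping multi-exon genes on 1–2 toy chromosomes with random
strands (an opposite-strand overlapping twin available for tie-break
tests); molecules placed uniformly on a disk-shaped tissue region
(radius = 0.35 × min(width, height)) over Poisson background (0.02
molecules per off-tissue spot); per-molecule PCR duplication
1 + Poisson(mean − 1); independent per-base substitution errors on
CID/MID/cDNA; and splice-aware SAM records placed at each fragment's true
genomic origin. Everything is deterministic under the seed.

Standard desk-scale conditions: 20 × 20 chip, 5 genes, 2,000 molecules,
CID/MID/cDNA error rates 1 % / 0.5 % / 0.5 %, duplication 5×, read length
100. What the generator does **not** emulate — indels, quality-correlated
errors, chimeras, multimapping, intronic (pre-mRNA) reads, platform error
profiles — bounds what passing tests show: they validate the arithmetic
and bookkeeping of every stage against exact ground truth, not robustness
to every artifact of real libraries.

## Problem sizes and numerics

Tests and the acceptance checks run on deliberately small instances chosen
to make exhaustive oracles feasible: masks up to 10⁴ entries against a
full Hamming scan, 500 randomized reads against per-base labeling, 10³
random correction groups, and the 20 × 20-chip end-to-end fixture
(~10⁴ reads). All stochastic assertions are seeded; binomial checks use
3σ bounds. Percentages in the run report are computed relative to the
count surviving the previous stage and rounded to two decimals.
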