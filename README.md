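# stereoflow

Desk-scale preprocessing for Stereo-seq-style spatial transcriptomics.
Sequencing reads carry a 25-base coordinate ID (CID) that identifies one
capture spot on a patterned chip and a 10-base molecular identity (MID, a
UMI) that distinguishes original mRNA molecules from PCR duplicates.
`stereoflow` turns raw FASTQ plus a chip mask and alignments into a spatial
gene-expression matrix:

1. **Spatial restoration** — each read's CID is matched against the mask
   (CID → (x, y)); a read that misses exactly is retried against all
   3 × 25 single-base substitution variants, so one sequencing error in the
   barcode still restores the position. Hits at two or more distinct spots
   are discarded as ambiguous. Masks and FASTQs can be partitioned by a CID
   prefix or modulo rule to bound memory; partitioned matching is exactly
   equivalent to whole-mask matching.
2. **Read QC** — drop reads whose MID contains N, is poly-A, or has a base
   below the Phred floor; trim trailing cDNA poly-A runs and drop reads
   left too short.
3. **Annotation** — alignments are decomposed into CIGAR blocks and scored
   per gene and transcript: a read is EXONIC when ≥ 50 % of its length
   overlaps exons, else INTRONIC when ≥ 50 % overlaps intron regions, else
   INTERGENIC. Among candidate genes the best label wins
   (EXONIC > INTRONIC > INTERGENIC), then the largest overlap, then the
   smallest (start, end). Antisense reads are tallied and excluded from the
   matrix.
4. **MID correction** — within each (spot, gene) group, MIDs sorted by
   descending count are traversed from rarest to most abundant; each merges
   into the first higher-ranked MID within Hamming distance 1 (defaults
   5 / 1 / 10 for the MID-type gate / tolerance / MID length). Counts are
   conserved exactly.
5. **Expression matrix** — unique corrected MIDs per (x, y, gene), written
   as plain-text GEM TSV and an HDF5 container; aggregable to bin-N
   lattices (e.g. bin200) by floor division.
6. **Tissue extraction** — the expression heatmap is segmented with a
   classical grayscale chain (log1p → Gaussian → Otsu → morphology → area
   filter → hole fill) and the matrix is subset to the tissue contour.
7. **Saturation** — reads expanded from (x, y, gene, MID, count) tuples are
   shuffled once; each sampling fraction f ∈ {0.05, 0.1, …, 1.0} takes a
   prefix and reports saturation = 1 − unique/total and the median genes
   per occupied bin at bin1 and bin200.

A synthetic-data module generates chips, reads, splice-aware alignments and
tissue geometry with full ground truth, so the whole pipeline is testable
without sequencer output.

## Worked example

Simulate a small run and process it end to end:

```bash
stereoflow simulate --width 12 --height 12 --genes 3 --molecules 300 \
    --seed 7 --outdir demo
cat > demo/pipeline.yaml <<EOF
mask_path: demo/mask.tsv
fastq1_path: demo/reads_1.fastq
fastq2_path: demo/reads_2.fastq
sam_path: demo/aln.sam
gtf_path: demo/genes.gtf
outdir: demo/run
seed: 7
EOF
stereoflow run --config demo/pipeline.yaml
```

The report (also written to `demo/run/report.json`) contains, among other
stages:

```json
"restore": {
  "total_reads": 1519,
  "exact_matches": 1168,
  "corrected_matches": 309,
  "ambiguous": 0,
  "unmatched": 42,
  "mapped_fraction": 0.9723502304147466
}
```

1,519 reads were simulated from 300 + background molecules at a 1 %
per-base CID error rate; 1,168 CIDs matched the mask exactly, 309 were
rescued by single-substitution correction, and 42 (mostly two-error
barcodes) were lost — 97.2 % restored overall, matching the closed form
(1−e)²⁵ + 25e(1−e)²⁴ ≈ 0.974 at e = 0.01. The matrix summary

```json
"matrix": {"records": 138, "total_mid_count": 340, "tissue_records": 136,
           "retained_count_fraction": 0.994}
```

says the run yielded 138 (x, y, gene) records totalling 340 unique
molecules, of which 99.4 % fall inside the segmented tissue disk.
`demo/run/` also holds `matrix.gem`, `matrix.h5`, `tissue.gem`, the tissue
mask PNG with contours, and `saturation.tsv`.

The same stages are available as library functions
(`stereoflow.restore_reads`, `correct_group`, `build_matrix`,
`segment_tissue`, `saturation_curve`, …) and as per-stage subcommands
(`stereoflow split | restore | midcorrect | simulate | run`).

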