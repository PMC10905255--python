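import numpy as np
import pytest

from stereoflow import (
    AlignBlock,
    AnnotationResult,
    GeneIndex,
    GeneModel,
    Transcript,
    annotate_blocks,
    annotate_read,
    load_gene_models,
    make_gene_models,
    parse_align_blocks,
    score_gene,
    tally_annotation,
)
from stereoflow.annotate import EXONIC, INTERGENIC, INTRONIC


def gene(gene_id, start, end, exons, strand="+", chrom="chr1"):
    return GeneModel(
        gene_id, chrom, strand, start, end,
        [Transcript(f"{gene_id}.t1", sorted(exons))],
    )


def per_base_counts(blocks, g):
    """Independent oracle: label every aligned base individually."""
    best = (0, 0)
    for tx in g.transcripts:
        exon_bases = {
            p for s, e in tx.exons for p in range(s, e)
        }
        exon = intron = 0
        for blk in blocks:
            for pos in range(blk.ref_start, blk.ref_end):
                if pos in exon_bases:
                    exon += 1
                elif g.start <= pos < g.end:
                    intron += 1
        best = max(best, (exon, intron))
    return best


class TestParseAlignBlocks:
    @pytest.mark.parametrize(
        "cigar, pos, exp_len, exp_blocks",
        [
            ("50M", 100, 50, [(100, 150)]),
            ("20M100N30M", 0, 50, [(0, 20), (120, 150)]),
            ("10S40M", 100, 50, [(100, 140)]),
            ("10M5D10M", 100, 20, [(100, 110), (115, 125)]),
            ("10M5I10M", 100, 25, [(100, 120)]),
            ("5H20M", 50, 20, [(50, 70)]),
            ("10=2X8M", 0, 20, [(0, 20)]),
        ],
    )
    def test_cigar_semantics(self, cigar, pos, exp_len, exp_blocks):
        read_len, blocks = parse_align_blocks(cigar, pos)
        assert read_len == exp_len
        assert [(b.ref_start, b.ref_end) for b in blocks] == exp_blocks

    @pytest.mark.parametrize("cigar", ["", "12", "M", "10Z", "10M3"])
    def test_malformed_cigar_rejected(self, cigar):
        with pytest.raises(ValueError):
            parse_align_blocks(cigar, 0)


class TestLoadGeneModels:
    def _write(self, tmp_path, text):
        path = tmp_path / "genes.gtf"
        path.write_text(text)
        return path

    def test_single_gene_single_exon(self, tmp_path):
        gtf = (
            'chr1\tx\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tx\texon\t101\t200\t.\t+\t.\t'
            'gene_id "g1"; transcript_id "g1.t1";\n'
        )
        index = load_gene_models(self._write(tmp_path, gtf))
        g = index.genes["g1"]
        # 1-based closed GTF -> 0-based half-open internal
        assert (g.start, g.end) == (100, 200)
        assert g.transcripts[0].exons == [(100, 200)]

    def test_overlapping_opposite_strand_genes_both_returned(self, tmp_path):
        genome = make_gene_models(2, seed=1, overlap=True)
        index = load_gene_models(self._write(tmp_path, genome.gtf_text))
        twin = genome.genes[-1]
        hits = index.overlapping(twin.chrom, twin.start, twin.end)
        ids = {g.gene_id for g in hits}
        assert {twin.gene_id, twin.gene_id.removesuffix("_as")} <= ids
        strands = {g.strand for g in hits}
        assert strands == {"+", "-"}

    def test_exon_outside_gene_span_rejected(self, tmp_path):
        gtf = (
            'chr1\tx\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tx\texon\t50\t120\t.\t+\t.\t'
            'gene_id "g1"; transcript_id "g1.t1";\n'
        )
        with pytest.raises(ValueError, match="outside gene"):
            load_gene_models(self._write(tmp_path, gtf))


class TestScoreGene:
    def test_read_fully_inside_exon(self):
        g = gene("g1", 0, 1000, [(100, 400)])
        exoncnt, introncnt, label = score_gene(
            [AlignBlock(150, 200, 0)], 50, g
        )
        assert (exoncnt, introncnt, label) == (50, 0, EXONIC)

    def test_mostly_intronic_read(self):
        # 20 bases in exon [100,400), 30 in the following intron
        g = gene("g1", 0, 1000, [(100, 400)])
        exoncnt, introncnt, label = score_gene(
            [AlignBlock(380, 430, 0)], 50, g
        )
        assert (exoncnt, introncnt, label) == (20, 30, INTRONIC)

    def test_both_below_half_is_intergenic(self):
        # 24 exonic + 24 intronic + 2 outside the gene span
        g = gene("g1", 100, 148, [(100, 124)])
        exoncnt, introncnt, label = score_gene(
            [AlignBlock(100, 150, 0)], 50, g
        )
        assert (exoncnt, introncnt) == (24, 24)
        assert label == INTERGENIC

    def test_transcript_maximization(self):
        # two transcripts; the one with more exon overlap wins
        g = GeneModel(
            "g1", "chr1", "+", 0, 1000,
            [
                Transcript("t_short", [(0, 10)]),
                Transcript("t_long", [(0, 50)]),
            ],
        )
        exoncnt, introncnt, label = score_gene([AlignBlock(0, 50, 0)], 50, g)
        assert (exoncnt, introncnt, label) == (50, 0, EXONIC)


def test_per_base_oracle_on_randomized_reads():
    """Interval-arithmetic counts equal per-base labeling for 500 random
    reads (single- and spliced-block) over toy gene models."""
    rng = np.random.default_rng(77)
    genome = make_gene_models(6, seed=77)
    genes = [
        GeneModel(g.gene_id, g.chrom, g.strand, g.start, g.end,
                  [Transcript(f"{g.gene_id}.t1", g.exons)])
        for g in genome.genes
    ]
    span = max(g.end for g in genes)
    for _ in range(500):
        g = genes[int(rng.integers(0, len(genes)))]
        start = int(rng.integers(max(0, g.start - 100), g.end + 100))
        if rng.random() < 0.5:
            length = int(rng.integers(1, 200))
            blocks = [AlignBlock(start, start + length, 0)]
        else:
            l1 = int(rng.integers(1, 100))
            gap = int(rng.integers(1, 300))
            l2 = int(rng.integers(1, 100))
            blocks = [
                AlignBlock(start, start + l1, 0),
                AlignBlock(start + l1 + gap, start + l1 + gap + l2, l1),
            ]
        read_length = sum(b.length for b in blocks)
        exoncnt, introncnt, _label = score_gene(blocks, read_length, g)
        assert (exoncnt, introncnt) == per_base_counts(blocks, g)


class TestGeneChoice:
    def test_exonic_beats_intronic(self):
        g_ex = gene("gA", 0, 500, [(0, 500)])
        g_in = gene("gB", 0, 500, [(400, 500)])
        index = GeneIndex([g_ex, g_in])
        res = annotate_blocks("chr1", [AlignBlock(0, 50, 0)], 50, "+", index)
        assert (res.gene_id, res.label) == ("gA", EXONIC)

    def test_larger_overlap_wins(self):
        # gA covers 40 bases of the read, gB covers all 50
        g_a = gene("gA", 0, 40, [(0, 40)])
        g_b = gene("gB", 0, 500, [(0, 500)])
        index = GeneIndex([g_a, g_b])
        res = annotate_blocks("chr1", [AlignBlock(0, 50, 0)], 50, "+", index)
        assert res.gene_id == "gB"
        assert res.overlap_len == 50

    def test_tie_broken_by_smallest_start(self):
        g1 = gene("g_late", 200, 700, [(200, 700)])
        g2 = gene("g_early", 100, 700, [(100, 700)])
        index = GeneIndex([g1, g2])
        res = annotate_blocks("chr1", [AlignBlock(300, 350, 0)], 50, "+", index)
        assert res.gene_id == "g_early"

    def test_no_overlap_is_intergenic_without_gene(self):
        index = GeneIndex([gene("g1", 0, 100, [(0, 100)])])
        res = annotate_blocks("chr1", [AlignBlock(5000, 5050, 0)], 50, "+", index)
        assert (res.label, res.gene_id) == (INTERGENIC, None)

    def test_antisense_flag_ignores_label(self):
        g = gene("g1", 0, 500, [(0, 500)], strand="-")
        index = GeneIndex([g])
        res = annotate_blocks("chr1", [AlignBlock(0, 50, 0)], 50, "+", index)
        assert res.label == EXONIC and res.antisense
        res2 = annotate_blocks("chr1", [AlignBlock(0, 50, 0)], 50, "-", index)
        assert res2.label == EXONIC and not res2.antisense


class TestAnnotateRead:
    def _record(self, line):
        import pysam

        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10000}]}
        )
        return pysam.AlignedSegment.fromstring(line, header)

    def test_uniquely_mapped_gating(self):
        index = GeneIndex([gene("g1", 0, 500, [(0, 500)])])
        base = "r1\t{flag}\tchr1\t101\t{mapq}\t50M\t*\t0\t0\t" + "A" * 50 + "\t*"
        primary = self._record(base.format(flag=0, mapq=255))
        secondary = self._record(base.format(flag=256, mapq=255))
        low_mapq = self._record(base.format(flag=0, mapq=3))
        assert annotate_read(primary, index).gene_id == "g1"
        assert annotate_read(secondary, index) is None
        assert annotate_read(low_mapq, index) is None


class TestTally:
    def test_transcriptome_is_exonic_plus_intronic(self):
        stream = [AnnotationResult(EXONIC, "g1")] * 3 + [
            AnnotationResult(INTRONIC, "g1")
        ] * 2
        stats = tally_annotation(stream)
        assert stats.transcriptome == 5
        assert (stats.exonic, stats.intronic, stats.intergenic) == (3, 2, 0)

    def test_empty_stream_all_zero(self):
        stats = tally_annotation([])
        assert stats.total == stats.transcriptome == stats.antisense == 0

    def test_label_partition_sums_to_total(self):
        rng = np.random.default_rng(1)
        labels = [
            (EXONIC, INTRONIC, INTERGENIC)[i] for i in rng.integers(0, 3, 50)
        ]
        stream = [
            AnnotationResult(lab, None if lab == INTERGENIC else "g",
                             antisense=bool(rng.integers(0, 2)))
            for lab in labels
        ]
        stats = tally_annotation(stream)
        assert stats.total == 50
        assert stats.exonic == labels.count(EXONIC)
        assert stats.intergenic == labels.count(INTERGENIC)
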