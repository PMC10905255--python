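"""Gene-region annotation of uniquely mapped alignments.

Each alignment is decomposed into reference blocks from its CIGAR, overlap
with every candidate gene is measured transcript by transcript, and the
read is labeled EXONIC if at least half its length overlaps exons of the
best transcript, INTRONIC if at least half overlaps that transcript's
intronic (gene-span minus exon) regions, and INTERGENIC otherwise.  Among
overlapping genes the best label wins (EXONIC > INTRONIC > INTERGENIC),
then the largest overlap, then the gene with the smallest (start, end).
Strand never affects the region label; it only sets the antisense flag,
which downstream excludes the read from the expression matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from intervaltree import IntervalTree

EXONIC = "EXONIC"
INTRONIC = "INTRONIC"
INTERGENIC = "INTERGENIC"

_LABEL_PRIORITY = {EXONIC: 2, INTRONIC: 1, INTERGENIC: 0}

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, disjoint


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span
    end: int
    transcripts: list[Transcript] = field(default_factory=list)


class GeneIndex:
    """Per-chromosome interval index over gene spans."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes:
            self.genes[gene.gene_id] = gene
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            tree.addi(gene.start, gene.end, gene.gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = {iv.data for iv in tree.overlap(start, end)}
        return [self.genes[g] for g in sorted(hits)]


def load_gene_models(path) -> GeneIndex:
    """Load gene/transcript/exon features from a GTF or GFF3 file.

    1-based closed annotation coordinates become internal 0-based
    half-open intervals.  Requires gene_id (and transcript_id on
    transcript/exon features); exons must lie inside their gene's span.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("gene_id", [None])[0]
        if gene_id is None:
            raise ValueError(f"gene feature at {feat.seqid}:{feat.start} lacks gene_id")
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene {gene_id} has unknown strand {feat.strand!r}")
        genes[gene_id] = GeneModel(
            gene_id, feat.seqid, feat.strand, feat.start - 1, feat.end
        )
    transcripts: dict[str, Transcript] = {}
    for feat in db.features_of_type("transcript"):
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [None])[0]
        if tid is None or gid is None:
            raise ValueError("transcript feature lacks transcript_id/gene_id")
        tx = Transcript(tid, [])
        transcripts[tid] = tx
        genes[gid].transcripts.append(tx)
    for feat in db.features_of_type("exon"):
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [None])[0]
        start, end = feat.start - 1, feat.end
        gene = genes[gid]
        if start < gene.start or end > gene.end:
            raise ValueError(
                f"exon [{start},{end}) outside gene {gid} span "
                f"[{gene.start},{gene.end})"
            )
        if tid not in transcripts:  # GTF without explicit transcript lines
            tx = Transcript(tid, [])
            transcripts[tid] = tx
            gene.transcripts.append(tx)
        transcripts[tid].exons.append((start, end))
    for tx in transcripts.values():
        tx.exons.sort()
    return GeneIndex(genes.values())


# ---------------------------------------------------------------------------
# CIGAR -> alignment blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignBlock:
    ref_start: int
    ref_end: int
    read_offset: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


def parse_align_blocks(cigar: str, ref_pos: int) -> tuple[int, list[AlignBlock]]:
    """Decompose a CIGAR at 0-based ref_pos into reference-aligned blocks.

    M/=/X extend the current block; N (splice) and D close it and advance
    the reference; I and S consume read only; H and P consume neither.
    read_length sums read-consuming ops (M/=/X/I/S).
    """
    consumed = sum(len(m.group(0)) for m in _CIGAR_RE.finditer(cigar))
    if consumed != len(cigar) or not cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    blocks: list[AlignBlock] = []
    ref = ref_pos
    read_off = 0
    read_length = 0
    cur_start: Optional[int] = None
    cur_read_off = 0
    for m in _CIGAR_RE.finditer(cigar):
        length, op = int(m.group(1)), m.group(2)
        if op in "M=X":
            if cur_start is None:
                cur_start = ref
                cur_read_off = read_off
            ref += length
            read_off += length
            read_length += length
        elif op in "ND":
            if cur_start is not None:
                blocks.append(AlignBlock(cur_start, ref, cur_read_off))
                cur_start = None
            ref += length
        elif op in "IS":
            if op == "I" and cur_start is not None:
                # insertion splits read offsets but not the reference block
                pass
            read_off += length
            read_length += length
        # H, P: no-op
    if cur_start is not None:
        blocks.append(AlignBlock(cur_start, ref, cur_read_off))
    return read_length, blocks


# ---------------------------------------------------------------------------
# Scoring and gene choice
# ---------------------------------------------------------------------------

def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def score_gene(
    blocks: Sequence[AlignBlock], read_length: int, gene: GeneModel
) -> tuple[int, int, str]:
    """Best (exoncnt, introncnt, label) of a read against one gene.

    Per transcript, exoncnt sums block overlap with exons and introncnt
    block overlap with the gene span outside that transcript's exons; the
    transcript maximizing (exoncnt, introncnt) represents the gene.  Label
    by the 50%-of-read-length rule.
    """
    best = (0, 0)
    for tx in gene.transcripts or [Transcript("__span__", [])]:
        exoncnt = 0
        genecnt = 0
        for blk in blocks:
            genecnt += _overlap(blk.ref_start, blk.ref_end, gene.start, gene.end)
            for es, ee in tx.exons:
                exoncnt += _overlap(blk.ref_start, blk.ref_end, es, ee)
        introncnt = genecnt - exoncnt
        if (exoncnt, introncnt) > best:
            best = (exoncnt, introncnt)
    exoncnt, introncnt = best
    half = 0.5 * read_length
    if exoncnt >= half:
        label = EXONIC
    elif introncnt >= half:
        label = INTRONIC
    else:
        label = INTERGENIC
    return exoncnt, introncnt, label


@dataclass
class AnnotationResult:
    label: str
    gene_id: Optional[str]
    exoncnt: int = 0
    introncnt: int = 0
    overlap_len: int = 0
    antisense: bool = False


def is_uniquely_mapped(rec, min_mapq: int = 20) -> bool:
    """Primary, non-supplementary, and MAPQ 255-style-unique or >= min_mapq."""
    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
        return False
    return rec.mapping_quality == 255 or rec.mapping_quality >= min_mapq


def annotate_blocks(
    chrom: str,
    blocks: Sequence[AlignBlock],
    read_length: int,
    read_strand: str,
    index: GeneIndex,
) -> AnnotationResult:
    """Annotate pre-parsed blocks (the core of :func:`annotate_read`)."""
    if not blocks:
        return AnnotationResult(INTERGENIC, None)
    span_start = min(b.ref_start for b in blocks)
    span_end = max(b.ref_end for b in blocks)
    candidates = []
    for gene in index.overlapping(chrom, span_start, span_end):
        exoncnt, introncnt, label = score_gene(blocks, read_length, gene)
        if exoncnt + introncnt == 0:
            continue
        candidates.append((gene, exoncnt, introncnt, label))
    if not candidates:
        return AnnotationResult(INTERGENIC, None)
    best_priority = max(_LABEL_PRIORITY[c[3]] for c in candidates)
    if best_priority == 0:
        # every overlapping gene scores below both 50% cuts
        return AnnotationResult(INTERGENIC, None)
    pool = [c for c in candidates if _LABEL_PRIORITY[c[3]] == best_priority]
    # largest overlap first; ties -> smallest (start, end, gene_id)
    gene, exoncnt, introncnt, label = min(
        pool,
        key=lambda c: (-(c[1] + c[2]), c[0].start, c[0].end, c[0].gene_id),
    )
    return AnnotationResult(
        label,
        gene.gene_id,
        exoncnt,
        introncnt,
        exoncnt + introncnt,
        antisense=(read_strand != gene.strand),
    )


def annotate_read(rec, index: GeneIndex, min_mapq: int = 20) -> Optional[AnnotationResult]:
    """Annotate a pysam alignment record; None if not uniquely mapped."""
    if not is_uniquely_mapped(rec, min_mapq):
        return None
    read_length, blocks = parse_align_blocks(rec.cigarstring, rec.reference_start)
    strand = "-" if rec.is_reverse else "+"
    return annotate_blocks(rec.reference_name, blocks, read_length, strand, index)


@dataclass
class AnnotationStats:
    exonic: int = 0
    intronic: int = 0
    intergenic: int = 0
    antisense: int = 0

    @property
    def transcriptome(self) -> int:
        return self.exonic + self.intronic

    @property
    def total(self) -> int:
        return self.exonic + self.intronic + self.intergenic

    def as_dict(self) -> dict:
        return {
            "exonic": self.exonic,
            "intronic": self.intronic,
            "intergenic": self.intergenic,
            "transcriptome": self.transcriptome,
            "antisense": self.antisense,
            "total": self.total,
        }


def tally_annotation(
    results: Iterable[AnnotationResult], stats: AnnotationStats | None = None
) -> AnnotationStats:
    """Region-label tallies; transcriptome = exonic + intronic, antisense
    counted separately (an antisense read still counts under its label)."""
    stats = stats or AnnotationStats()
    for res in results:
        if res.label == EXONIC:
            stats.exonic += 1
        elif res.label == INTRONIC:
            stats.intronic += 1
        else:
            stats.intergenic += 1
        if res.antisense and res.gene_id is not None:
            stats.antisense += 1
    return stats
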