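"""End-to-end orchestration: split/restore → filter → annotate → MID
correction → matrix → tissue extraction → saturation → report.

The pipeline is a thin, deterministic driver over the stage modules.  Reads
are streamed in batches (``batch_size`` bounds memory, never results), the
mask may be partitioned (``n_partitions``; partitioned and unpartitioned
matching give identical output), and every stage writes its statistics so
the final report can show the funnel with percentages relative to the
previous stage.  Alignment itself is pluggable: the pipeline consumes any
SAM/BAM whose read names match the FASTQ, real or simulated.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional

import pandas as pd

from . import annotate as anno_mod
from .annotate import (
    AnnotationStats,
    annotate_read,
    load_gene_models,
    tally_annotation,
)
from .chip_mask import PartitionRule, parse_fastq_pairs, load_mask
from .cid_restore import RestoreStats, build_cid_index, restore_reads
from .expr_matrix import (
    ExpressionMatrix,
    build_matrix,
    bin_matrix,
    stage_report,
    write_matrix,
    write_report,
)
from .mid_correct import (
    CorrectionParams,
    CorrectionStats,
    apply_mapping,
    correct_all,
)
from .read_qc import FilterParams, FilterStats, filter_batch
from .saturation import (
    DEFAULT_FRACTIONS,
    sample_coordinates,
    saturation_curve,
    write_saturation_tsv,
)
from .tissuecut import (
    SegmentationParams,
    expression_to_heatmap,
    extract_tissue_records,
    segment_tissue,
    write_contours_tsv,
    write_mask_png,
)


@dataclass
class PipelineConfig:
    """All stage parameters plus I/O paths for one run."""

    mask_path: str = ""
    fastq1_path: str = ""
    fastq2_path: Optional[str] = None
    sam_path: str = ""
    gtf_path: str = ""
    outdir: str = "stereoflow_run"

    n_partitions: int = 1
    partition_mode: str = "prefix"  # prefix for powers of 4, else modulo
    batch_size: int = 100_000
    seed: int = 0

    filter_params: FilterParams = field(default_factory=FilterParams)
    correction_params: CorrectionParams = field(default_factory=CorrectionParams)
    segmentation_params: SegmentationParams = field(
        default_factory=SegmentationParams
    )
    min_mapq: int = 20
    matrix_bin_sizes: tuple[int, ...] = ()
    tissue_bin_size: int = 1
    saturation_bin_size: int = 200
    saturation_coord_fraction: float = 0.05
    saturation_fractions: tuple[float, ...] = DEFAULT_FRACTIONS

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("filter_params", FilterParams),
            ("correction_params", CorrectionParams),
            ("segmentation_params", SegmentationParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        for key in ("matrix_bin_sizes", "saturation_fractions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def partition_rule_for(n_partitions: int, mode: str = "prefix") -> PartitionRule:
    """A valid rule for the requested part count: prefix when n is a power
    of 4 (and prefix mode requested), modulo otherwise."""
    if n_partitions == 1:
        return PartitionRule(1, "modulo")
    if mode == "prefix":
        prefix_len = 0
        n = n_partitions
        while n % 4 == 0:
            n //= 4
            prefix_len += 1
        if n == 1:
            return PartitionRule(n_partitions, "prefix", prefix_len)
    return PartitionRule(n_partitions, "modulo")


def _batched(iterable, size):
    it = iter(iterable)
    while True:
        chunk = list(itertools.islice(it, size))
        if not chunk:
            return
        yield chunk


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    tissue_matrix: ExpressionMatrix
    saturation: Optional[pd.DataFrame]
    report: dict
    outdir: str


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order and write all outputs under ``outdir``."""
    os.makedirs(config.outdir, exist_ok=True)

    # --- restore: CID matching against the (possibly partitioned) mask
    mask = load_mask(config.mask_path)
    rule = partition_rule_for(config.n_partitions, config.partition_mode)
    index = build_cid_index(mask, rule if rule.n_parts > 1 else None)
    restore_stats = RestoreStats()
    filter_stats = FilterStats()
    fparams = config.filter_params
    # read_id -> (x, y, mid); only located reads passing QC
    passed: dict[str, tuple[int, int, str]] = {}
    reads = parse_fastq_pairs(config.fastq1_path, config.fastq2_path)
    for chunk in _batched(reads, config.batch_size):
        located = (
            lr
            for lr in restore_reads(chunk, index, restore_stats)
            if lr.matched
        )
        for lr, _outcome in filter_batch(located, fparams, filter_stats):
            passed[lr.read.read_id] = (
                lr.coordinate.x,
                lr.coordinate.y,
                lr.read.mid,
            )

    # --- annotation against gene models
    import pysam

    models = load_gene_models(config.gtf_path)
    anno_stats = AnnotationStats()
    align_total = 0
    unique_total = 0
    # per-read annotated tuples: (x, y, gene, mid, antisense)
    annotated: list[tuple[int, int, str, str, bool]] = []
    with pysam.AlignmentFile(config.sam_path, check_sq=False) as sam:
        for rec in sam:
            if rec.query_name not in passed:
                continue
            align_total += 1
            result = annotate_read(rec, models, config.min_mapq)
            if result is None:
                continue
            unique_total += 1
            tally_annotation([result], anno_stats)
            if result.gene_id is not None and result.label in (
                anno_mod.EXONIC,
                anno_mod.INTRONIC,
            ):
                x, y, mid = passed[rec.query_name]
                annotated.append((x, y, result.gene_id, mid, result.antisense))

    # --- MID correction per (coordinate, gene) group
    groups: dict[tuple[int, int, str], dict[str, int]] = {}
    for x, y, gene, mid, _anti in annotated:
        groups.setdefault((x, y, gene), {}).setdefault(mid, 0)
        groups[(x, y, gene)][mid] += 1
    corr_stats = CorrectionStats()
    corrections = correct_all(groups, config.correction_params, corr_stats)

    # --- expression matrix from sense reads with corrected MIDs
    tuples = [
        (x, y, gene, apply_mapping(mid, corrections[(x, y, gene)].mapping))
        for x, y, gene, mid, anti in annotated
        if not anti
    ]
    matrix = build_matrix(tuples, chip_name=mask.chip.name)
    write_matrix(matrix, os.path.join(config.outdir, "matrix.gem"))
    write_matrix(
        matrix, os.path.join(config.outdir, "matrix.h5"), format="container"
    )
    for bsize in config.matrix_bin_sizes:
        write_matrix(
            bin_matrix(matrix, bsize),
            os.path.join(config.outdir, f"matrix.bin{bsize}.gem"),
        )

    # --- tissue extraction from the expression heatmap
    heatmap = expression_to_heatmap(
        matrix, config.tissue_bin_size, mask.chip.width, mask.chip.height
    )
    tissue = segment_tissue(heatmap, config.segmentation_params)
    tissue_matrix, coverage = extract_tissue_records(matrix, tissue)
    write_matrix(tissue_matrix, os.path.join(config.outdir, "tissue.gem"))
    write_mask_png(tissue, os.path.join(config.outdir, "tissue_mask.png"))
    write_contours_tsv(tissue, os.path.join(config.outdir, "tissue_contours.tsv"))

    # --- saturation over tissue-region read tuples
    saturation = None
    tissue_keys = set(
        zip(tissue_matrix.records["x"], tissue_matrix.records["y"])
    )
    raw = pd.DataFrame(
        [
            (x, y, gene, apply_mapping(mid, corrections[(x, y, gene)].mapping))
            for x, y, gene, mid, anti in annotated
            if not anti and (x, y) in tissue_keys
        ],
        columns=["x", "y", "geneID", "mid"],
    )
    if not raw.empty:
        tuples_df = (
            raw.groupby(["x", "y", "geneID", "mid"], sort=True)
            .size()
            .reset_index(name="count")
        )
        sampled = sample_coordinates(
            tuples_df,
            config.saturation_coord_fraction,
            config.saturation_bin_size,
            config.seed,
        )
        saturation = saturation_curve(
            sampled,
            config.saturation_fractions,
            seed=config.seed,
            bin_size=config.saturation_bin_size,
        )
        write_saturation_tsv(
            saturation, os.path.join(config.outdir, "saturation.tsv")
        )

    # --- report
    report = stage_report(
        restore_stats=restore_stats.as_dict(),
        filter_stats=filter_stats.as_dict(),
        alignment_stats={
            "total": align_total,
            "uniquely_mapped": unique_total,
        },
        annotation_stats=anno_stats.as_dict(),
        correction_stats=corr_stats.as_dict(),
        matrix_summary={
            "records": len(matrix),
            "total_mid_count": matrix.total_count,
            "tissue_records": len(tissue_matrix),
            **coverage,
        },
    )
    write_report(report, os.path.join(config.outdir, "report.json"))
    return PipelineResult(matrix, tissue_matrix, saturation, report, config.outdir)
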