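"""Synthetic chips, reads, alignments and expression with known truth.

The generator stands in for the wet lab: it draws a chip mask (one unique
CID per lattice spot), a toy genome with multi-exon gene models on both
strands, and a set of mRNA molecules concentrated on a compact "tissue"
region over sparse background.  Each molecule is PCR-duplicated into reads
whose CID/MID/cDNA carry independent per-base substitution errors, and
every read is emitted both as a FASTQ pair and as a splice-aware SAM
record placed at its true genomic origin.  The truth tables trace every
read to its molecule, so every pipeline stage can be scored exactly.

Everything is deterministic under the seed: sub-streams for the mask, the
genes, molecule placement and read errors are spawned from one
SeedSequence, and regenerating with the same parameters reproduces
byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .chip_mask import (
    BASES,
    ChipSpec,
    LatticeCoordinate,
    MaskTable,
    SequencedRead,
)

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

HIGH_QUAL = "F"  # Phred 37


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for a synthetic run.

    Defaults describe the standard desk-scale fixture: a 20x20-spot chip,
    5 genes, 2,000 molecules on a disk-shaped tissue region covering ~35%
    of the chip radius, 1% CID / 0.5% MID / 0.5% cDNA per-base substitution
    rates and a mean PCR duplication of 5x.
    """

    chip: ChipSpec = ChipSpec("synthchip", 20, 20, 25)
    n_genes: int = 5
    n_molecules: int = 2000
    cid_error_rate: float = 0.01
    mid_error_rate: float = 0.005
    cdna_error_rate: float = 0.005
    duplication_mean: float = 5.0
    mid_length: int = 10
    read_length: int = 100
    tissue_shape: str = "disk"  # disk | rectangle | none
    tissue_radius_fraction: float = 0.35
    background_rate: float = 0.02  # molecules per off-tissue spot
    antisense_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.cid_error_rate, self.mid_error_rate,
                     self.cdna_error_rate):
            if not 0 <= rate < 1:
                raise ValueError("error rates must be in [0, 1)")
        if self.duplication_mean < 1:
            raise ValueError("duplication_mean must be >= 1")
        if self.tissue_shape not in ("disk", "rectangle", "none"):
            raise ValueError(f"unknown tissue_shape {self.tissue_shape!r}")


# ---------------------------------------------------------------------------
# Chip mask
# ---------------------------------------------------------------------------

def _random_seqs(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=(n, length), dtype=np.uint8)


def _codes_to_strings(codes: np.ndarray) -> list[str]:
    return [bytes(_BASE_ARR[row]).decode() for row in codes]


def make_chip(
    chip: ChipSpec, seed: int, min_pairwise_distance: int = 3,
    _max_rounds: int = 50,
) -> MaskTable:
    """Draw one distinct CID per lattice spot, deterministically.

    For chips small enough to check (≤ 5,000 spots) CIDs are resampled
    until every pair is at Hamming distance ≥ ``min_pairwise_distance``,
    so single-substitution rescue is unambiguous by construction.
    """
    n = chip.n_points
    if 4 ** chip.cid_length < n:
        raise ValueError("chip too large for cid_length")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1D]))
    codes = _random_seqs(rng, n, chip.cid_length)
    if n <= 5000 and min_pairwise_distance > 1:
        for _ in range(_max_rounds):
            bad = _too_close(codes, min_pairwise_distance)
            if not bad.any():
                break
            codes[bad] = _random_seqs(rng, int(bad.sum()), chip.cid_length)
        else:
            raise RuntimeError("could not satisfy the CID distance constraint")
    mask = MaskTable(chip)
    cids = _codes_to_strings(codes)
    if len(set(cids)) != n:
        raise RuntimeError("CID collision survived resampling")
    i = 0
    for y in range(chip.height):
        for x in range(chip.width):
            mask.entries[cids[i]] = LatticeCoordinate(x, y)
            i += 1
    return mask


def _too_close(codes: np.ndarray, min_dist: int) -> np.ndarray:
    """Boolean row mask of CIDs violating the pairwise distance floor."""
    n = len(codes)
    bad = np.zeros(n, dtype=bool)
    chunk = 512
    for i in range(0, n, chunk):
        block = codes[i : i + chunk]
        dist = (block[:, None, :] != codes[None, :, :]).sum(axis=2)
        dist[np.arange(len(block)), i + np.arange(len(block))] = codes.shape[1]
        hit = (dist < min_dist).any(axis=1)
        bad[i : i + chunk] = hit
    return bad


# ---------------------------------------------------------------------------
# Toy genome + gene models
# ---------------------------------------------------------------------------

@dataclass
class ToyGene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int
    exons: list[tuple[int, int]]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    genes: list[ToyGene]
    gtf_text: str


def make_gene_models(
    n_genes: int, seed: int, overlap: bool = False
) -> ToyGenome:
    """Place non-overlapping multi-exon genes on 1–2 toy chromosomes.

    With ``overlap=True`` the last gene is duplicated on the opposite
    strand over the same span (for tie-break testing).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E4E]))
    chroms = ["chr1"] if n_genes <= 3 else ["chr1", "chr2"]
    genes: list[ToyGene] = []
    cursors = {c: 200 for c in chroms}
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        pos = cursors[chrom]
        n_exons = int(rng.integers(2, 4))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(150, 400))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(100, 500))
        start = exons[0][0]
        end = exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(ToyGene(f"g{i + 1}", chrom, strand, start, end, exons))
        cursors[chrom] = end + int(rng.integers(300, 800))
    if overlap and genes:
        last = genes[-1]
        twin_strand = "-" if last.strand == "+" else "+"
        genes.append(
            ToyGene(f"{last.gene_id}_as", last.chrom, twin_strand,
                    last.start, last.end, list(last.exons))
        )
    sequences = {}
    for chrom in chroms:
        length = cursors[chrom] + 200
        sequences[chrom] = bytes(
            _BASE_ARR[rng.integers(0, 4, size=length, dtype=np.uint8)]
        ).decode()
    return ToyGenome(sequences, genes, _genes_to_gtf(genes))


def _genes_to_gtf(genes: list[ToyGene]) -> str:
    lines = []
    for g in genes:
        attrs = f'gene_id "{g.gene_id}";'
        lines.append(
            f"{g.chrom}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        tid = f"{g.gene_id}.t1"
        tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
        lines.append(
            f"{g.chrom}\tsynth\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{tattrs}"
        )
        for s, e in g.exons:
            lines.append(
                f"{g.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Molecules and reads
# ---------------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, list[int]]:
    """Per-base substitution with the stated rate; returns (seq, positions)."""
    if rate <= 0:
        return seq, []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        current = arr[pos]
        choices = [b for b in _BASE_ARR if b != current]
        arr[pos] = choices[int(rng.integers(0, len(choices)))]
    return bytes(arr).decode(), hits.tolist()


def _fragment_blocks(
    gene: ToyGene, frag_start: int, frag_len: int
) -> list[tuple[int, int]]:
    """Genomic blocks of a fragment given in spliced-transcript coordinates."""
    blocks = []
    offset = 0
    remaining_start = frag_start
    remaining = frag_len
    for s, e in gene.exons:
        ex_len = e - s
        if remaining <= 0:
            break
        if remaining_start >= ex_len:
            remaining_start -= ex_len
            continue
        take_start = s + remaining_start
        take = min(ex_len - remaining_start, remaining)
        blocks.append((take_start, take_start + take))
        remaining -= take
        remaining_start = 0
    return blocks


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


@dataclass
class SimulationResult:
    params: SimulationParams
    mask: MaskTable
    genome: ToyGenome
    reads: list[SequencedRead]
    sam_text: str
    molecules: pd.DataFrame  # molecule_id, x, y, gene_id, mid, dup_count, antisense
    read_truth: pd.DataFrame  # read_id, molecule_id, cid_errors, mid_errors

    @property
    def gtf_text(self) -> str:
        return self.genome.gtf_text


def simulate_run(params: SimulationParams) -> SimulationResult:
    """Generate a full synthetic sequencing run with ground truth."""
    chip = params.chip
    mask = make_chip(chip, params.seed)
    genome = make_gene_models(params.n_genes, params.seed)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5EED]))

    coord_to_cid = {coord: cid for cid, coord in mask.entries.items()}
    tissue = tissue_truth_mask(params)
    in_coords = [LatticeCoordinate(x, y)
                 for y in range(chip.height) for x in range(chip.width)
                 if tissue[y, x]]
    out_coords = [LatticeCoordinate(x, y)
                  for y in range(chip.height) for x in range(chip.width)
                  if not tissue[y, x]]

    # molecule placement: n_molecules on tissue, Poisson background off it
    placements: list[LatticeCoordinate] = []
    if in_coords:
        idx = rng.integers(0, len(in_coords), size=params.n_molecules)
        placements.extend(in_coords[i] for i in idx)
    n_bg = (
        int(rng.poisson(params.background_rate * len(out_coords)))
        if out_coords else 0
    )
    if n_bg:
        idx = rng.integers(0, len(out_coords), size=n_bg)
        placements.extend(out_coords[i] for i in idx)

    genes = genome.genes
    mol_rows = []
    reads: list[SequencedRead] = []
    sam_lines = []
    truth_rows = []
    read_no = 0
    for mol_id, coord in enumerate(placements):
        gene = genes[int(rng.integers(0, len(genes)))]
        mid = bytes(
            _BASE_ARR[rng.integers(0, 4, size=params.mid_length, dtype=np.uint8)]
        ).decode()
        dup = 1 + int(rng.poisson(params.duplication_mean - 1.0))
        antisense = bool(rng.random() < params.antisense_fraction)
        frag_len = min(params.read_length, gene.spliced_length)
        frag_start = int(rng.integers(0, gene.spliced_length - frag_len + 1))
        blocks = _fragment_blocks(gene, frag_start, frag_len)
        cigar = _blocks_to_cigar(blocks)
        chrom_seq = genome.sequences[gene.chrom]
        genomic_seq = "".join(chrom_seq[s:e] for s, e in blocks)
        # alignment strand: sense reads follow the gene strand
        aln_strand = gene.strand if not antisense else (
            "-" if gene.strand == "+" else "+"
        )
        mol_rows.append(
            (mol_id, coord.x, coord.y, gene.gene_id, mid, dup, antisense)
        )
        true_cid = coord_to_cid[coord]
        for _ in range(dup):
            read_id = f"r{read_no:08d}"
            read_no += 1
            cid, cid_err = _mutate(true_cid, params.cid_error_rate, rng)
            rmid, mid_err = _mutate(mid, params.mid_error_rate, rng)
            seq, _ = _mutate(genomic_seq, params.cdna_error_rate, rng)
            # the sequenced cDNA read is the mRNA strand
            fastq_seq = seq if gene.strand == "+" else _revcomp(seq)
            if antisense:
                fastq_seq = _revcomp(fastq_seq)
            reads.append(
                SequencedRead(
                    read_id, cid, rmid, fastq_seq,
                    HIGH_QUAL * len(cid), HIGH_QUAL * len(rmid),
                    HIGH_QUAL * len(fastq_seq),
                )
            )
            flag = 16 if aln_strand == "-" else 0
            sam_lines.append(
                f"{read_id}\t{flag}\t{gene.chrom}\t{blocks[0][0] + 1}\t255\t"
                f"{cigar}\t*\t0\t0\t{seq}\t{HIGH_QUAL * len(seq)}"
            )
            truth_rows.append((read_id, mol_id, len(cid_err), len(mid_err)))

    header = ["@HD\tVN:1.6\tSO:unsorted"] + [
        f"@SQ\tSN:{chrom}\tLN:{len(seq)}"
        for chrom, seq in genome.sequences.items()
    ]
    sam_text = "\n".join(header + sam_lines) + "\n"
    molecules = pd.DataFrame(
        mol_rows,
        columns=["molecule_id", "x", "y", "gene_id", "mid", "dup_count",
                 "antisense"],
    )
    read_truth = pd.DataFrame(
        truth_rows, columns=["read_id", "molecule_id", "cid_errors", "mid_errors"]
    )
    return SimulationResult(
        params, mask, genome, reads, sam_text, molecules, read_truth
    )


def make_mid_groups(
    n_groups: int,
    molecules_per_group: int,
    duplication_mean: float = 5.0,
    mid_error_rate: float = 0.005,
    mid_length: int = 10,
    seed: int = 0,
) -> tuple[dict[int, dict[str, int]], dict[int, int]]:
    """Synthesize (coordinate, gene)-style MID groups with known truth.

    Each group holds a fixed number of true molecules with distinct random
    MIDs; every molecule is duplicated (1 + Poisson(mean − 1) reads) and
    each read's MID carries independent per-base substitution errors.
    Returns ({group: {observed MID: read count}}, {group: true unique MIDs}).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6709]))
    groups: dict[int, dict[str, int]] = {}
    truth: dict[int, int] = {}
    for g in range(n_groups):
        true_mids = set()
        while len(true_mids) < molecules_per_group:
            true_mids.add(
                bytes(
                    _BASE_ARR[rng.integers(0, 4, size=mid_length, dtype=np.uint8)]
                ).decode()
            )
        counts: dict[str, int] = {}
        for mid in sorted(true_mids):
            dup = 1 + int(rng.poisson(duplication_mean - 1.0))
            for _ in range(dup):
                observed, _err = _mutate(mid, mid_error_rate, rng)
                counts[observed] = counts.get(observed, 0) + 1
        groups[g] = counts
        truth[g] = len(true_mids)
    return groups, truth


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def tissue_truth_mask(params: SimulationParams) -> np.ndarray:
    """Ground-truth tissue raster (bin1) implied by the tissue geometry."""
    chip = params.chip
    yy, xx = np.mgrid[0 : chip.height, 0 : chip.width]
    if params.tissue_shape == "none":
        return np.ones((chip.height, chip.width), dtype=bool)
    if params.tissue_shape == "disk":
        cx, cy = (chip.width - 1) / 2, (chip.height - 1) / 2
        r = params.tissue_radius_fraction * min(chip.width, chip.height)
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    # rectangle: central half of each axis
    return (
        (xx >= chip.width // 4) & (xx < 3 * chip.width // 4)
        & (yy >= chip.height // 4) & (yy < 3 * chip.height // 4)
    )


def truth_matrix(result: SimulationResult):
    """Expected bin1 expression matrix: unique true MIDs per (x, y, gene),
    excluding antisense molecules (the matrix keeps sense reads only)."""
    from .expr_matrix import build_matrix

    mols = result.molecules
    sense = mols.loc[~mols["antisense"]]
    return build_matrix(
        list(zip(sense["x"], sense["y"], sense["gene_id"], sense["mid"])),
        chip_name=result.params.chip.name,
    )


def write_run(result: SimulationResult, outdir) -> dict:
    """Write mask.tsv, FASTQ pair, aln.sam, genes.gtf and truth tables."""
    import os

    from .chip_mask import write_fastq, write_mask

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "mask": os.path.join(outdir, "mask.tsv"),
        "fastq1": os.path.join(outdir, "reads_1.fastq"),
        "fastq2": os.path.join(outdir, "reads_2.fastq"),
        "sam": os.path.join(outdir, "aln.sam"),
        "gtf": os.path.join(outdir, "genes.gtf"),
        "molecules": os.path.join(outdir, "truth_molecules.tsv"),
        "read_truth": os.path.join(outdir, "truth_reads.tsv"),
    }
    write_mask(result.mask, paths["mask"])
    write_fastq(result.reads, paths["fastq1"], paths["fastq2"])
    with open(paths["sam"], "w", newline="\n") as fh:
        fh.write(result.sam_text)
    with open(paths["gtf"], "w", newline="\n") as fh:
        fh.write(result.gtf_text)
    result.molecules.to_csv(paths["molecules"], sep="\t", index=False)
    result.read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
    return paths
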