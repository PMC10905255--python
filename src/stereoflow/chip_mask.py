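"""Chip and mask data model, mask I/O, and CID-keyed partitioning.

A Stereo-seq style chip is a rectangular lattice of barcoded capture spots.
Each spot carries a coordinate ID (CID), a fixed-length DNA barcode that is
unique on the chip; the *mask* is the lookup table pairing every CID with
its (x, y) lattice coordinate.  Because a full-size chip mask is far too
large to hold in one hash table, both the mask and the FASTQ reads can be
partitioned by a shared, deterministic rule on the CID (a base prefix, or a
modulo of the CID's integer encoding) so that each partition pair can be
matched independently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, NamedTuple, Sequence

BASES = "ACGT"
#: fixed base-to-integer encoding, big-endian over the sequence
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

MASK_FORMAT_VERSION = 1


class LatticeCoordinate(NamedTuple):
    """A bin1 lattice position; x is the column, y the row, both 0-based."""

    x: int
    y: int


@dataclass(frozen=True)
class ChipSpec:
    """Geometry of a chip: name, lattice extent (bin1 units) and CID length."""

    name: str
    width: int
    height: int
    cid_length: int = 25

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("chip width and height must be positive")
        if self.cid_length <= 0:
            raise ValueError("cid_length must be positive")

    @property
    def n_points(self) -> int:
        return self.width * self.height

    def contains(self, coord: LatticeCoordinate) -> bool:
        return 0 <= coord.x < self.width and 0 <= coord.y < self.height


class MaskError(ValueError):
    """Raised for malformed or inconsistent mask files."""


@dataclass
class MaskTable:
    """Injective association CID -> LatticeCoordinate for one chip.

    ``entries`` maps each CID string (length ``chip.cid_length``, alphabet
    ACGT) to its lattice coordinate.  No CID appears twice and no two CIDs
    share a coordinate.
    """

    chip: ChipSpec
    entries: dict[str, LatticeCoordinate] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, cid: str, coord: LatticeCoordinate) -> None:
        self._check_cid(cid)
        if cid in self.entries:
            raise MaskError(f"duplicate CID in mask: {cid}")
        if not self.chip.contains(coord):
            raise MaskError(
                f"coordinate {tuple(coord)} outside chip "
                f"{self.chip.width}x{self.chip.height} for CID {cid}"
            )
        self.entries[cid] = coord

    def _check_cid(self, cid: str) -> None:
        if len(cid) != self.chip.cid_length:
            raise MaskError(
                f"CID {cid!r} has length {len(cid)}, "
                f"expected {self.chip.cid_length}"
            )
        if any(b not in BASE_CODE for b in cid):
            raise MaskError(f"CID {cid!r} contains non-ACGT characters")


@dataclass(frozen=True)
class PartitionRule:
    """How masks and reads are partitioned by CID.

    mode="prefix" classifies by the first ``prefix_len`` bases (requires
    ``n_parts == 4**prefix_len``); mode="modulo" classifies by the 2-bit
    integer encoding of the full CID modulo ``n_parts``.
    """

    n_parts: int
    mode: str = "prefix"
    prefix_len: int = 1

    def __post_init__(self) -> None:
        if self.n_parts < 1:
            raise ValueError("n_parts must be >= 1")
        if self.mode not in ("prefix", "modulo"):
            raise ValueError(f"unknown partition mode {self.mode!r}")
        if self.mode == "prefix" and self.n_parts != 4**self.prefix_len:
            raise ValueError(
                f"prefix mode requires n_parts = 4^prefix_len, got "
                f"n_parts={self.n_parts}, prefix_len={self.prefix_len}"
            )


def encode_cid(cid: str) -> int:
    """2-bit integer encoding of a CID, A=0 C=1 G=2 T=3, big-endian."""
    value = 0
    for base in cid:
        value = (value << 2) | BASE_CODE[base]
    return value


def assign_partition(cid: str, rule: PartitionRule) -> int:
    """Deterministic partition index in [0, n_parts) for a CID.

    CIDs containing N (or any non-ACGT symbol) cannot be encoded; they fall
    back to partition 0 — such reads can never match a mask entry exactly
    anyway, and distance-1 rescue across partitions handles the rest.
    """
    if rule.n_parts == 1:
        return 0
    if rule.mode == "prefix":
        prefix = cid[: rule.prefix_len]
        if any(b not in BASE_CODE for b in prefix):
            return 0
        return encode_cid(prefix)
    if any(b not in BASE_CODE for b in cid):
        return 0
    return encode_cid(cid) % rule.n_parts


def split_mask(mask: MaskTable, rule: PartitionRule) -> list[MaskTable]:
    """Partition a mask into ``rule.n_parts`` disjoint masks.

    Partition i holds exactly the entries whose CID has
    ``assign_partition(cid, rule) == i``; the union equals the input.
    """
    parts = [MaskTable(mask.chip) for _ in range(rule.n_parts)]
    for cid, coord in mask.entries.items():
        parts[assign_partition(cid, rule)].entries[cid] = coord
    return parts


def split_reads(
    reads: Iterable["SequencedRead"], rule: PartitionRule
) -> tuple[list[list["SequencedRead"]], list[tuple["SequencedRead", str]]]:
    """Route reads to partitions by their CID; returns (streams, rejects).

    Each read lands in exactly one stream, input order preserved within a
    stream.  Reads whose CID is shorter than expected go to the reject list
    with a reason.
    """
    streams: list[list[SequencedRead]] = [[] for _ in range(rule.n_parts)]
    rejects: list[tuple[SequencedRead, str]] = []
    for read in reads:
        if rule.mode == "prefix" and len(read.cid) < rule.prefix_len:
            rejects.append((read, "cid_too_short"))
            continue
        streams[assign_partition(read.cid, rule)].append(read)
    return streams, rejects


# ---------------------------------------------------------------------------
# Mask I/O — simple versioned TSV: a '#chip=...' header then CID<TAB>x<TAB>y
# ---------------------------------------------------------------------------

def _open_text(path, mode: str) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, mode + "b"), newline="\n")
    return open(path, mode, newline="\n")


def write_mask(mask: MaskTable, destination) -> None:
    """Write a mask as sorted TSV; round-trips through :func:`load_mask`."""
    chip = mask.chip
    with _open_text(destination, "w") as fh:
        fh.write(
            f"#chip={chip.name} width={chip.width} height={chip.height} "
            f"cid_length={chip.cid_length} version={MASK_FORMAT_VERSION}\n"
        )
        for cid in sorted(mask.entries):
            x, y = mask.entries[cid]
            fh.write(f"{cid}\t{x}\t{y}\n")


def load_mask(source) -> MaskTable:
    """Load a mask TSV, enforcing every MaskTable invariant."""
    with _open_text(source, "r") as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise MaskError("mask file missing '#chip=...' header line")
        fields = dict(
            item.split("=", 1) for item in header.lstrip("#").split() if "=" in item
        )
        try:
            chip = ChipSpec(
                name=fields["chip"],
                width=int(fields["width"]),
                height=int(fields["height"]),
                cid_length=int(fields["cid_length"]),
            )
        except KeyError as exc:
            raise MaskError(f"mask header missing field {exc}") from exc
        mask = MaskTable(chip)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MaskError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            cid, xs, ys = parts
            try:
                coord = LatticeCoordinate(int(xs), int(ys))
            except ValueError as exc:
                raise MaskError(f"line {lineno}: bad coordinate {xs!r},{ys!r}") from exc
            mask.add(cid, coord)
    return mask


# ---------------------------------------------------------------------------
# Read container + FASTQ layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadLayout:
    """Where the CID and MID sit in read 1 (cDNA is read 2, or the rest)."""

    cid_length: int = 25
    mid_length: int = 10


@dataclass
class SequencedRead:
    """One read after layout extraction: CID + MID (+ qualities) and cDNA."""

    read_id: str
    cid: str
    mid: str
    cdna_seq: str
    cid_qual: str
    mid_qual: str
    cdna_qual: str


def parse_fastq_pairs(
    read1_path, read2_path=None, layout: ReadLayout | None = None
) -> Iterator[SequencedRead]:
    """Stream SequencedReads from FASTQ(.gz).

    With two files, read 1 carries CID+MID and read 2 the cDNA.  With a
    single file, the bases after CID+MID are the cDNA.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    layout = layout or ReadLayout()
    c, m = layout.cid_length, layout.mid_length
    with _open_text(read1_path, "r") as fh1:
        it1 = FastqGeneralIterator(fh1)
        if read2_path is None:
            for title, seq, qual in it1:
                read_id = title.split()[0]
                yield SequencedRead(
                    read_id,
                    seq[:c], seq[c : c + m], seq[c + m :],
                    qual[:c], qual[c : c + m], qual[c + m :],
                )
        else:
            with _open_text(read2_path, "r") as fh2:
                for (t1, s1, q1), (t2, s2, q2) in zip(
                    it1, FastqGeneralIterator(fh2), strict=True
                ):
                    yield SequencedRead(
                        t1.split()[0],
                        s1[:c], s1[c : c + m], s2,
                        q1[:c], q1[c : c + m], q2,
                    )


def write_fastq(reads: Iterable[SequencedRead], read1_path, read2_path) -> None:
    """Write reads back out as a FASTQ pair (read1 = CID+MID, read2 = cDNA)."""
    with _open_text(read1_path, "w") as fh1, _open_text(read2_path, "w") as fh2:
        for r in reads:
            fh1.write(f"@{r.read_id}\n{r.cid}{r.mid}\n+\n{r.cid_qual}{r.mid_qual}\n")
            fh2.write(f"@{r.read_id}\n{r.cdna_seq}\n+\n{r.cdna_qual}\n")
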