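"""Spatial position restoration: match read CIDs to the chip mask.

Sequencers make errors, so a read's CID may differ from the chip's true
barcode.  The tolerance strategy is single-substitution rescue: if a CID is
not in the mask, every variant obtained by replacing one base with each of
the other three bases is queried.  Exactly one hit restores the read
(``corrected``); hits at two or more distinct coordinates are discarded as
``ambiguous``; no hit leaves the read ``unmatched``.

The same logic runs over a partitioned mask: a read is looked up in its
home partition, and single-base variants are routed to whichever partition
each variant belongs to, so partitioned matching is exactly equivalent to
matching against the whole mask — including for reads whose one error falls
inside the partitioning prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .chip_mask import (
    BASES,
    LatticeCoordinate,
    MaskTable,
    PartitionRule,
    SequencedRead,
    assign_partition,
    split_mask,
)

EXACT = "exact"
CORRECTED = "corrected"
UNMATCHED = "unmatched"
AMBIGUOUS = "ambiguous"


@dataclass
class LocatedRead:
    read: SequencedRead
    coordinate: Optional[LatticeCoordinate]
    match_kind: str
    mismatch_position: Optional[int] = None

    @property
    def matched(self) -> bool:
        return self.match_kind in (EXACT, CORRECTED)


@dataclass
class RestoreStats:
    total_reads: int = 0
    exact_matches: int = 0
    corrected_matches: int = 0
    ambiguous: int = 0
    unmatched: int = 0

    @property
    def mapped_fraction(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return (self.exact_matches + self.corrected_matches) / self.total_reads

    def count(self, kind: str) -> None:
        self.total_reads += 1
        if kind == EXACT:
            self.exact_matches += 1
        elif kind == CORRECTED:
            self.corrected_matches += 1
        elif kind == AMBIGUOUS:
            self.ambiguous += 1
        else:
            self.unmatched += 1

    def as_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "exact_matches": self.exact_matches,
            "corrected_matches": self.corrected_matches,
            "ambiguous": self.ambiguous,
            "unmatched": self.unmatched,
            "mapped_fraction": self.mapped_fraction,
        }


class CIDIndex:
    """Exact + distance-1 CID lookup over one mask (hash-table backed).

    Memory is proportional to the mask; a distance-1 query tests the
    3 × cid_length single-substitution variants against the table, which is
    equivalent to an exhaustive Hamming scan of the whole mask.
    """

    def __init__(self, mask: MaskTable):
        self.cid_length = mask.chip.cid_length
        self._table = dict(mask.entries)

    def __len__(self) -> int:
        return len(self._table)

    def exact(self, cid: str) -> Optional[LatticeCoordinate]:
        return self._table.get(cid)

    def locate(self, cid: str) -> tuple[str, Optional[LatticeCoordinate], Optional[int]]:
        """Classify a query CID: exact / corrected / ambiguous / unmatched."""
        if len(cid) != self.cid_length:
            raise ValueError(
                f"query CID length {len(cid)} != index cid_length {self.cid_length}"
            )
        hit = self._table.get(cid)
        if hit is not None:
            return EXACT, hit, None
        hits: list[tuple[LatticeCoordinate, int]] = []
        for pos, base in enumerate(cid):
            for alt in BASES:
                if alt == base:
                    continue
                coord = self._table.get(cid[:pos] + alt + cid[pos + 1 :])
                if coord is not None:
                    hits.append((coord, pos))
                    if len(hits) > 1:
                        return AMBIGUOUS, None, None
        if len(hits) == 1:
            coord, pos = hits[0]
            return CORRECTED, coord, pos
        return UNMATCHED, None, None


class PartitionedCIDIndex:
    """CID lookup over a partitioned mask, equivalent to a single index.

    Exact lookups go to the read's home partition.  Variant lookups are
    routed per variant: a substitution outside the partitioning prefix
    stays in the home partition, one inside the prefix is queried in the
    partition that variant encodes to.  This preserves reads whose single
    CID error falls inside the prefix.
    """

    def __init__(self, mask: MaskTable, rule: PartitionRule):
        self.rule = rule
        self.cid_length = mask.chip.cid_length
        self._parts = [dict(p.entries) for p in split_mask(mask, rule)]

    def __len__(self) -> int:
        return sum(len(p) for p in self._parts)

    def exact(self, cid: str) -> Optional[LatticeCoordinate]:
        return self._parts[assign_partition(cid, self.rule)].get(cid)

    def locate(self, cid: str) -> tuple[str, Optional[LatticeCoordinate], Optional[int]]:
        if len(cid) != self.cid_length:
            raise ValueError(
                f"query CID length {len(cid)} != index cid_length {self.cid_length}"
            )
        hit = self.exact(cid)
        if hit is not None:
            return EXACT, hit, None
        hits: list[tuple[LatticeCoordinate, int]] = []
        for pos, base in enumerate(cid):
            for alt in BASES:
                if alt == base:
                    continue
                variant = cid[:pos] + alt + cid[pos + 1 :]
                coord = self._parts[assign_partition(variant, self.rule)].get(variant)
                if coord is not None:
                    hits.append((coord, pos))
                    if len(hits) > 1:
                        return AMBIGUOUS, None, None
        if len(hits) == 1:
            coord, pos = hits[0]
            return CORRECTED, coord, pos
        return UNMATCHED, None, None


def build_cid_index(
    mask: MaskTable, rule: PartitionRule | None = None
) -> CIDIndex | PartitionedCIDIndex:
    """Build the lookup index; a rule with n_parts > 1 yields a partitioned one."""
    if rule is None or rule.n_parts == 1:
        return CIDIndex(mask)
    return PartitionedCIDIndex(mask, rule)


def locate_cid(index, cid: str):
    """Functional alias for ``index.locate(cid)``."""
    return index.locate(cid)


def restore_reads(
    reads: Iterable[SequencedRead], index, stats: RestoreStats | None = None
) -> Iterator[LocatedRead]:
    """Locate every read; one LocatedRead per input, order preserved.

    Pass a RestoreStats to accumulate the restoration funnel counters
    (exact + corrected + ambiguous + unmatched = total).
    """
    for read in reads:
        try:
            kind, coord, pos = index.locate(read.cid)
        except ValueError:
            kind, coord, pos = UNMATCHED, None, None
        if stats is not None:
            stats.count(kind)
        yield LocatedRead(read, coord, kind, pos)
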