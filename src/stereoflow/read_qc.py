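"""Pre-alignment read filters on spatially located reads.

Checks applied in fixed order, first failure reported:

1. MID contains an N base;
2. MID is poly-A (every base A);
3. any MID base below the Phred quality floor;
4. a trailing poly-A run in the cDNA of at least ``polya_run_min`` bases is
   trimmed, and the read fails if the remaining cDNA is too short.

Poly-A in the cDNA is trimmed rather than discarded outright: a poly-A tail
is expected biology, and only reads left with too little informative
sequence are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .cid_restore import LocatedRead

PHRED_OFFSET = 33

REASON_NONE = "none"
REASON_MID_N = "mid_has_N"
REASON_MID_POLYA = "mid_polyA"
REASON_MID_QUAL = "mid_low_quality"
REASON_CDNA_SHORT = "cdna_too_short_after_polyA_trim"

FAIL_REASONS = (REASON_MID_N, REASON_MID_POLYA, REASON_MID_QUAL, REASON_CDNA_SHORT)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the pre-alignment filters.

    min_mid_quality: per-base Phred floor for the MID (default 10).
    polya_run_min: minimal trailing A-run length that triggers trimming.
    min_cdna_length_after_trim: minimal informative cDNA length to keep.
    """

    min_mid_quality: int = 10
    polya_run_min: int = 10
    min_cdna_length_after_trim: int = 25

    def __post_init__(self) -> None:
        if min(self.min_mid_quality, self.polya_run_min,
               self.min_cdna_length_after_trim) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FilterOutcome:
    passed: bool
    reason: str
    trimmed_cdna: str


@dataclass
class FilterStats:
    total: int = 0
    passed: int = 0
    failed: dict = field(default_factory=lambda: {r: 0 for r in FAIL_REASONS})

    @property
    def retained_fraction(self) -> float:
        return self.passed / self.total if self.total else 0.0

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "passed": self.passed,
            "failed": dict(self.failed),
            "retained_fraction": self.retained_fraction,
        }


def trailing_polya_run(seq: str) -> int:
    """Length of the maximal trailing run of A bases."""
    n = 0
    for base in reversed(seq):
        if base != "A":
            break
        n += 1
    return n


def filter_read(read: LocatedRead, params: FilterParams) -> FilterOutcome:
    """Apply the ordered filter chain to one located read."""
    mid = read.read.mid
    if "N" in mid:
        return FilterOutcome(False, REASON_MID_N, read.read.cdna_seq)
    if mid and set(mid) == {"A"}:
        return FilterOutcome(False, REASON_MID_POLYA, read.read.cdna_seq)
    floor = params.min_mid_quality
    if any(ord(q) - PHRED_OFFSET < floor for q in read.read.mid_qual):
        return FilterOutcome(False, REASON_MID_QUAL, read.read.cdna_seq)
    cdna = read.read.cdna_seq
    run = trailing_polya_run(cdna)
    trimmed = cdna[: len(cdna) - run] if run >= params.polya_run_min else cdna
    if len(trimmed) < params.min_cdna_length_after_trim:
        return FilterOutcome(False, REASON_CDNA_SHORT, trimmed)
    return FilterOutcome(True, REASON_NONE, trimmed)


def filter_batch(
    reads: Iterable[LocatedRead],
    params: FilterParams,
    stats: FilterStats | None = None,
) -> Iterator[tuple[LocatedRead, FilterOutcome]]:
    """Filter a stream; yields only passing reads (with their trimmed cDNA).

    Counters satisfy passed + sum(failed per reason) = total.
    """
    for read in reads:
        outcome = filter_read(read, params)
        if stats is not None:
            stats.total += 1
            if outcome.passed:
                stats.passed += 1
            else:
                stats.failed[outcome.reason] += 1
        if outcome.passed:
            yield read, outcome
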