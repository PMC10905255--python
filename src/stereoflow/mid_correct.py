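"""MID (molecular identity / UMI) error correction by count-ordered merging.

Reads sharing a (coordinate, gene) key are grouped by their MID; sequencing
errors inflate the number of distinct MIDs.  Within each group the MIDs are
sorted by descending count and traversed from the rarest toward the most
abundant: each MID is compared, in rank order, against the MIDs ranked
above it, and merges its count into the first one within the Hamming
tolerance.  Groups with fewer MID species than ``min_mid_types`` are left
untouched.  Counts are conserved exactly; no new MID is ever created.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Mapping


@dataclass(frozen=True)
class CorrectionParams:
    """min_mid_types / tolerance / mid_length, default 5 / 1 / 10."""

    min_mid_types: int = 5
    tolerance: int = 1
    mid_length: int = 10


@dataclass
class CorrectionResult:
    corrected_counts: dict[str, int]
    mapping: dict[str, str]  # merged-away MID -> surviving MID


@dataclass
class CorrectionStats:
    groups: int = 0
    groups_corrected: int = 0
    mids_merged: int = 0
    counts_moved: int = 0

    def as_dict(self) -> dict:
        return {
            "groups": self.groups,
            "groups_corrected": self.groups_corrected,
            "mids_merged": self.mids_merged,
            "counts_moved": self.counts_moved,
        }


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"MID length mismatch: {a!r} vs {b!r}")
    return sum(x != y for x, y in zip(a, b))


def correct_group(
    counts: Mapping[str, int], params: CorrectionParams = CorrectionParams()
) -> CorrectionResult:
    """Correct one {MID: count} group.

    Sort order is descending count with ties broken by descending
    lexicographic MID, which fixes a deterministic rank for every MID.
    Traversal runs from the lowest rank upward; each MID m scans ranks
    0..rank(m)-1 in order and merges into the first MID within the
    tolerance (merged-away MIDs keep their rank and stay valid targets;
    the mapping is not chained).  Ranks never change as counts move.
    """
    lengths = {len(m) for m in counts}
    if len(lengths) > 1:
        raise ValueError(f"mixed MID lengths in group: {sorted(lengths)}")
    if len(counts) < params.min_mid_types:
        return CorrectionResult(dict(counts), {})
    order = sorted(counts, key=lambda m: (-counts[m], _desc_key(m)))
    current = {m: counts[m] for m in order}
    mapping: dict[str, str] = {}
    for i in range(len(order) - 1, 0, -1):
        m = order[i]
        for j in range(i):
            target = order[j]
            if hamming(m, target) <= params.tolerance:
                current[target] += current[m]
                current[m] = 0
                mapping[m] = target
                break
    return CorrectionResult(current, mapping)


def _desc_key(mid: str) -> str:
    # descending lexicographic via complemented characters
    return "".join(chr(255 - ord(c)) for c in mid)


def correct_all(
    groups: Mapping[Hashable, Mapping[str, int]],
    params: CorrectionParams = CorrectionParams(),
    stats: CorrectionStats | None = None,
) -> dict[Hashable, CorrectionResult]:
    """Correct every (coordinate, gene) group independently."""
    out: dict[Hashable, CorrectionResult] = {}
    for key, counts in groups.items():
        result = correct_group(counts, params)
        out[key] = result
        if stats is not None:
            stats.groups += 1
            if result.mapping:
                stats.groups_corrected += 1
                stats.mids_merged += len(result.mapping)
                stats.counts_moved += sum(
                    counts[old] for old in result.mapping
                )
    return out


def apply_mapping(mid: str, mapping: Mapping[str, str]) -> str:
    """Resolve one read's MID through a group's correction mapping.

    Chains are followed: a merge target may itself have merged into a more
    abundant MID later in the traversal (each step moves strictly up the
    rank order, so resolution terminates).  Replaying the resolved mapping
    over the raw per-read MID list reproduces the corrected counts exactly.
    """
    while mid in mapping:
        mid = mapping[mid]
    return mid
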