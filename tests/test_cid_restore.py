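import numpy as np
import pytest

from stereoflow import (
    ChipSpec,
    LatticeCoordinate,
    MaskTable,
    PartitionRule,
    RestoreStats,
    SequencedRead,
    build_cid_index,
    locate_cid,
    make_chip,
    restore_reads,
)
from stereoflow.cid_restore import AMBIGUOUS, CORRECTED, EXACT, UNMATCHED

from conftest import random_cids, tiny_mask

_B2I = {"A": 0, "C": 1, "G": 2, "T": 3}


def brute_force_scan(mask, query):
    """Independent oracle: exhaustive Hamming scan of the whole mask."""
    best = {0: [], 1: []}
    for cid, coord in mask.entries.items():
        d = sum(a != b for a, b in zip(cid, query))
        if d <= 1:
            best[d].append(coord)
    if best[0]:
        return EXACT, best[0][0]
    if len(best[1]) == 1:
        return CORRECTED, best[1][0]
    if len(best[1]) > 1:
        return AMBIGUOUS, None
    return UNMATCHED, None


def _mutate(rng, cid, n_subs):
    pos = rng.choice(len(cid), size=n_subs, replace=False)
    out = list(cid)
    for p in pos:
        out[p] = "ACGT"[(_B2I[out[p]] + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _read(cid, read_id="r"):
    return SequencedRead(read_id, cid, "ACGTACGTAC", "A" * 30,
                         "F" * len(cid), "F" * 10, "F" * 30)


class TestLocateCid:
    def test_exact_hit(self):
        mask = tiny_mask(["AAAA", "CCCC"], cid_length=4)
        index = build_cid_index(mask)
        assert locate_cid(index, "AAAA") == (EXACT, LatticeCoordinate(0, 0), None)

    def test_single_substitution_corrected_with_position(self):
        mask = tiny_mask(["AAAA", "CCCC"], cid_length=4)
        index = build_cid_index(mask)
        kind, coord, pos = locate_cid(index, "AGAA")
        assert (kind, coord, pos) == (CORRECTED, LatticeCoordinate(0, 0), 1)

    def test_two_neighbours_at_distinct_coords_is_ambiguous(self):
        # query ATAA is distance 1 from both AAAA (pos 1) and ATAT (pos 3)
        mask = tiny_mask(["AAAA", "ATAT"], cid_length=4)
        index = build_cid_index(mask)
        assert locate_cid(index, "ATAA") == (AMBIGUOUS, None, None)
        assert brute_force_scan(mask, "ATAA")[0] == AMBIGUOUS

    def test_n_blocks_exact_but_allows_correction(self):
        mask = tiny_mask(["AAAA"], cid_length=4)
        index = build_cid_index(mask)
        kind, coord, pos = locate_cid(index, "ANAA")
        assert (kind, coord, pos) == (CORRECTED, LatticeCoordinate(0, 0), 1)

    def test_empty_mask_never_matches(self):
        index = build_cid_index(MaskTable(ChipSpec("e", 2, 2, 4)))
        assert locate_cid(index, "ACGT") == (UNMATCHED, None, None)

    def test_wrong_length_raises(self):
        index = build_cid_index(tiny_mask(["AAAA"], cid_length=4))
        with pytest.raises(ValueError):
            locate_cid(index, "AAA")


@pytest.mark.parametrize(
    "rule",
    [None, PartitionRule(4, "prefix", 1), PartitionRule(16, "prefix", 2),
     PartitionRule(7, "modulo")],
    ids=["flat", "prefix4", "prefix16", "modulo7"],
)
def test_oracle_equivalence_random_mask(rule):
    """Indexed lookup agrees with the exhaustive Hamming scan — including
    for partitioned indexes, where a prefix error crosses partitions."""
    rng = np.random.default_rng(123)
    chip = ChipSpec("o", 50, 40, 25)
    mask = MaskTable(chip)
    cids = random_cids(rng, 2000)
    coords = [(i % 50, i // 50) for i in range(2000)]
    for cid, (x, y) in zip(cids, coords):
        mask.entries[cid] = LatticeCoordinate(x, y)
    index = build_cid_index(mask, rule)
    for _ in range(300):
        base = cids[int(rng.integers(0, len(cids)))]
        n_subs = int(rng.integers(0, 3))
        query = _mutate(rng, base, n_subs)
        kind, coord, _pos = index.locate(query)
        assert (kind, coord) == brute_force_scan(mask, query)


class TestRestoreReads:
    def test_error_free_reads_all_exact(self):
        mask = make_chip(ChipSpec("c", 10, 10, 25), seed=5)
        index = build_cid_index(mask)
        reads = [_read(cid, f"r{i}") for i, cid in enumerate(mask.entries)]
        stats = RestoreStats()
        located = list(restore_reads(reads, index, stats))
        assert stats.exact_matches == stats.total_reads == 100
        assert stats.mapped_fraction == 1.0
        assert [lr.read.read_id for lr in located] == [r.read_id for r in reads]
        for lr, (cid, coord) in zip(located, mask.entries.items()):
            assert lr.coordinate == coord

    def test_single_substitution_reads_all_corrected(self):
        # pairwise distance >= 3 makes every 1-substitution variant unique
        mask = make_chip(ChipSpec("c", 10, 10, 25), seed=5)
        index = build_cid_index(mask)
        rng = np.random.default_rng(9)
        reads = [_read(_mutate(rng, cid, 1)) for cid in mask.entries]
        stats = RestoreStats()
        list(restore_reads(reads, index, stats))
        assert stats.corrected_matches == 100
        assert stats.ambiguous == stats.unmatched == 0

    def test_counter_conservation_on_mixed_stream(self):
        mask = make_chip(ChipSpec("c", 8, 8, 25), seed=2)
        index = build_cid_index(mask)
        rng = np.random.default_rng(4)
        cids = list(mask.entries)
        reads = [
            _read(_mutate(rng, cids[i % len(cids)], i % 4)) for i in range(80)
        ]
        stats = RestoreStats()
        located = list(restore_reads(reads, index, stats))
        assert (
            stats.exact_matches + stats.corrected_matches
            + stats.ambiguous + stats.unmatched
            == stats.total_reads == len(located) == 80
        )
        # only exact/corrected reads carry a coordinate
        for lr in located:
            assert lr.matched == (lr.coordinate is not None)

    def test_determinism(self):
        mask = make_chip(ChipSpec("c", 8, 8, 25), seed=2)
        index = build_cid_index(mask)
        rng = np.random.default_rng(4)
        reads = [_read(_mutate(rng, cid, 1)) for cid in mask.entries]
        first = [(lr.match_kind, lr.coordinate, lr.mismatch_position)
                 for lr in restore_reads(reads, index)]
        second = [(lr.match_kind, lr.coordinate, lr.mismatch_position)
                  for lr in restore_reads(reads, index)]
        assert first == second
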