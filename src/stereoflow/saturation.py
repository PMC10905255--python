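"""Sequencing-saturation and median-gene curves by read subsampling.

Saturation at a subsampling fraction is 1 − (unique (x, y, gene, MID)
tuples / total reads): it approaches 1 when additional sequencing only
reproduces molecules already seen.  The per-read list is expanded from
(x, y, gene, MID, count) tuples, shuffled once, and each fraction takes a
prefix of the shuffle, so rows are nested and distinct-tuple counts are
non-decreasing across fractions.  Median genes per bin is the median, over
occupied bins only, of the number of distinct genes in a bin, on the bin1
and bin200 lattices.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_FRACTIONS = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

TUPLE_COLUMNS = ["x", "y", "geneID", "mid", "count"]


@dataclass
class SaturationRow:
    fraction: float
    total_reads: int
    saturation_bin1: float
    saturation_bin200: float
    median_genes_bin1: float
    median_genes_bin200: float


def sample_coordinates(
    tuples: pd.DataFrame, frac: float, bin_size: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Sample a fraction of occupied bin200 bins; keep tuples in those bins.

    The number of sampled bins is the ceiling of frac × occupied bins, so a
    non-empty input never samples to nothing.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if tuples.empty:
        raise ValueError("empty tuple list")
    bins = pd.DataFrame(
        {
            "bx": tuples["x"].to_numpy() // bin_size,
            "by": tuples["y"].to_numpy() // bin_size,
        }
    )
    uniq = bins.drop_duplicates().sort_values(["bx", "by"]).to_numpy()
    n_take = min(len(uniq), ceil(frac * len(uniq)))
    rng = np.random.default_rng(seed)
    chosen = uniq[rng.choice(len(uniq), size=n_take, replace=False)]
    chosen_set = {tuple(row) for row in chosen}
    keep = [
        (bx, by) in chosen_set for bx, by in zip(bins["bx"], bins["by"])
    ]
    return tuples.loc[keep].reset_index(drop=True)


def saturation_curve(
    tuples: pd.DataFrame,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    bin200_resolution_keys: bool = False,
    bin_size: int = 200,
) -> pd.DataFrame:
    """Compute the saturation table over nested subsampling prefixes.

    ``tuples`` has columns x, y, geneID, mid, count; count is the pre-dedup
    read count of that molecule.  With ``bin200_resolution_keys`` the
    bin200 saturation deduplicates on (bin200, gene, MID) instead of the
    bin1 key (under the plain reading both columns are identical).
    """
    if tuples.empty or tuples["count"].sum() == 0:
        raise ValueError("empty read list")
    reads = tuples.loc[
        np.repeat(tuples.index.to_numpy(), tuples["count"].to_numpy())
    ].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    reads = reads.iloc[rng.permutation(len(reads))].reset_index(drop=True)
    x = reads["x"].to_numpy()
    y = reads["y"].to_numpy()
    gene = reads["geneID"].to_numpy()
    mid = reads["mid"].to_numpy()
    n = len(reads)
    rows = []
    for frac in sorted(fractions):
        k = max(1, floor(frac * n))
        sub = pd.DataFrame(
            {"x": x[:k], "y": y[:k], "geneID": gene[:k], "mid": mid[:k]}
        )
        uniq_bin1 = len(sub.drop_duplicates())
        sat1 = 1.0 - uniq_bin1 / k
        if bin200_resolution_keys:
            sub200 = sub.copy()
            sub200["x"] //= bin_size
            sub200["y"] //= bin_size
            sat200 = 1.0 - len(sub200.drop_duplicates()) / k
        else:
            sat200 = sat1
        dedup = sub.drop_duplicates()
        mg1 = float(
            dedup.groupby(["x", "y"])["geneID"].nunique().median()
        )
        d200 = dedup.copy()
        d200["x"] //= bin_size
        d200["y"] //= bin_size
        mg200 = float(
            d200.groupby(["x", "y"])["geneID"].nunique().median()
        )
        rows.append(
            SaturationRow(frac, k, sat1, sat200, mg1, mg200)
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def write_saturation_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")
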