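"""Spatial gene-expression matrix: build, bin, serialize, and report.

The matrix is the table of unique corrected-MID counts per (x, y, gene):
only EXONIC/INTRONIC, sense-strand reads contribute, PCR duplicates having
been collapsed through MID correction.  bin1 records aggregate to coarser
lattices (e.g. bin200) by floor-dividing coordinates and summing counts.
Two on-disk forms are supported: a plain-text "gem" TSV and an HDF5
container (/expression/{gene,x,y,count} + /metadata attributes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

GEM_COLUMNS = ["geneID", "x", "y", "MIDCount"]
MATRIX_FORMAT_VERSION = 1


@dataclass
class ExpressionMatrix:
    """Long-form spatial expression table with (x, y, geneID) unique rows."""

    records: pd.DataFrame  # columns geneID, x, y, MIDCount
    chip_name: str = ""
    bin_size: int = 1

    def __post_init__(self) -> None:
        df = self.records
        if list(df.columns) != GEM_COLUMNS:
            df = df.loc[:, GEM_COLUMNS]
        self.records = _canonical(df)

    @property
    def total_count(self) -> int:
        return int(self.records["MIDCount"].sum())

    def __len__(self) -> int:
        return len(self.records)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.records.reset_index(drop=True).equals(
            other.records.reset_index(drop=True)
        )


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    df = df.astype(
        {"geneID": str, "x": np.int64, "y": np.int64, "MIDCount": np.int64}
    )
    return df.sort_values(["x", "y", "geneID"], kind="mergesort").reset_index(
        drop=True
    )


def build_matrix(
    read_tuples: Iterable[tuple[int, int, str, str]],
    chip_name: str = "",
) -> ExpressionMatrix:
    """Count unique MIDs per (x, y, gene) from (x, y, gene, corrected MID)
    read tuples that already passed the exonic/intronic + sense selection."""
    df = pd.DataFrame(read_tuples, columns=["x", "y", "geneID", "mid"])
    if df.empty:
        empty = pd.DataFrame(columns=GEM_COLUMNS)
        return ExpressionMatrix(empty, chip_name=chip_name)
    counts = (
        df.drop_duplicates()
        .groupby(["x", "y", "geneID"], sort=False)
        .size()
        .reset_index(name="MIDCount")
    )
    return ExpressionMatrix(counts[GEM_COLUMNS], chip_name=chip_name)


def bin_matrix(matrix: ExpressionMatrix, bin_size: int) -> ExpressionMatrix:
    """Aggregate to a coarser lattice; counts are summed per (bin, gene).

    Bin coordinates are bin indices (floor division); the input must be at
    bin1.  bin_size=1 is the identity.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if matrix.bin_size != 1:
        raise ValueError("bin_matrix expects a bin1 matrix")
    if bin_size == 1 or matrix.records.empty:
        return ExpressionMatrix(
            matrix.records.copy(), matrix.chip_name, bin_size=bin_size
        )
    df = matrix.records.copy()
    df["x"] = df["x"] // bin_size
    df["y"] = df["y"] // bin_size
    out = (
        df.groupby(["geneID", "x", "y"], sort=False)["MIDCount"]
        .sum()
        .reset_index()
    )
    return ExpressionMatrix(out[GEM_COLUMNS], matrix.chip_name, bin_size=bin_size)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_matrix(matrix: ExpressionMatrix, path, format: str = "gem-tsv") -> None:
    if format == "gem-tsv":
        _write_gem(matrix, path)
    elif format == "container":
        _write_h5(matrix, path)
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_matrix(path, format: str | None = None) -> ExpressionMatrix:
    path = str(path)
    if format is None:
        format = "container" if path.endswith((".h5", ".hdf5", ".gef")) else "gem-tsv"
    return _read_h5(path) if format == "container" else _read_gem(path)


def _write_gem(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(
            f"#chip={matrix.chip_name} bin_size={matrix.bin_size} "
            f"version={MATRIX_FORMAT_VERSION}\n"
        )
        fh.write("\t".join(GEM_COLUMNS) + "\n")
        for row in matrix.records.itertuples(index=False):
            fh.write(f"{row.geneID}\t{row.x}\t{row.y}\t{row.MIDCount}\n")


def _read_gem(path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError("gem file missing metadata header")
        meta = dict(
            item.split("=", 1) for item in header.lstrip("#").split() if "=" in item
        )
        if int(meta.get("version", 1)) != MATRIX_FORMAT_VERSION:
            raise ValueError(f"unsupported gem version {meta.get('version')}")
        df = pd.read_csv(fh, sep="\t")
    if list(df.columns) != GEM_COLUMNS:
        raise ValueError(f"unexpected gem columns {list(df.columns)}")
    return ExpressionMatrix(
        df, chip_name=meta.get("chip", ""), bin_size=int(meta.get("bin_size", 1))
    )


def _write_h5(matrix: ExpressionMatrix, path) -> None:
    import h5py

    df = matrix.records
    with h5py.File(path, "w") as f:
        grp = f.create_group("expression")
        gene_ds = grp.create_dataset(
            "gene", shape=(len(df),), dtype=h5py.string_dtype()
        )
        if len(df):
            gene_ds[:] = df["geneID"].astype(str).to_numpy()
        grp.create_dataset("x", data=df["x"].to_numpy(np.int64))
        grp.create_dataset("y", data=df["y"].to_numpy(np.int64))
        grp.create_dataset("count", data=df["MIDCount"].to_numpy(np.int64))
        meta = f.create_group("metadata")
        meta.attrs["chip"] = matrix.chip_name
        meta.attrs["bin_size"] = matrix.bin_size
        meta.attrs["version"] = MATRIX_FORMAT_VERSION


def _read_h5(path) -> ExpressionMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        meta = f["metadata"].attrs
        if int(meta["version"]) != MATRIX_FORMAT_VERSION:
            raise ValueError(f"unsupported container version {meta['version']}")
        df = pd.DataFrame(
            {
                "geneID": [g.decode() for g in f["expression/gene"][()]],
                "x": f["expression/x"][()],
                "y": f["expression/y"][()],
                "MIDCount": f["expression/count"][()],
            }
        )
        return ExpressionMatrix(
            df[GEM_COLUMNS] if len(df) else pd.DataFrame(columns=GEM_COLUMNS),
            chip_name=str(meta["chip"]),
            bin_size=int(meta["bin_size"]),
        )


# ---------------------------------------------------------------------------
# Run report (stage funnel)
# ---------------------------------------------------------------------------

def stage_report(
    restore_stats: Optional[Mapping] = None,
    filter_stats: Optional[Mapping] = None,
    alignment_stats: Optional[Mapping] = None,
    annotation_stats: Optional[Mapping] = None,
    correction_stats: Optional[Mapping] = None,
    matrix_summary: Optional[Mapping] = None,
) -> dict:
    """Assemble the per-stage funnel; every percentage is relative to the
    count surviving the previous stage.  Missing stages appear as null."""

    def pct(numer, denom):
        return round(100.0 * numer / denom, 2) if denom else 0.0

    report: dict = {"stages": {}}
    prev = None
    if restore_stats is not None:
        total = restore_stats["total_reads"]
        mapped = restore_stats["exact_matches"] + restore_stats["corrected_matches"]
        report["stages"]["restore"] = {
            **dict(restore_stats),
            "mapped_pct_vs_previous": pct(mapped, total),
        }
        prev = mapped
    else:
        report["stages"]["restore"] = None
    if filter_stats is not None:
        passed = filter_stats["passed"]
        report["stages"]["filter"] = {
            **dict(filter_stats),
            "retained_pct_vs_previous": pct(passed, prev if prev is not None
                                            else filter_stats["total"]),
        }
        prev = passed
    else:
        report["stages"]["filter"] = None
    if alignment_stats is not None:
        uniq = alignment_stats["uniquely_mapped"]
        report["stages"]["alignment"] = {
            **dict(alignment_stats),
            "unique_pct_vs_previous": pct(uniq, prev if prev is not None
                                          else alignment_stats.get("total", 0)),
        }
        prev = uniq
    else:
        report["stages"]["alignment"] = None
    report["stages"]["annotation"] = (
        dict(annotation_stats) if annotation_stats is not None else None
    )
    report["stages"]["mid_correction"] = (
        dict(correction_stats) if correction_stats is not None else None
    )
    report["stages"]["matrix"] = (
        dict(matrix_summary) if matrix_summary is not None else None
    )
    return report


def write_report(report: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
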