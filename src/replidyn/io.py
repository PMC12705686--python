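"""Readers and writers for the package's plain-text formats.

Genomic tracks travel as 4-column bedGraph-like TSVs (chrom, start, end,
value), expression and state matrices as TSVs with feature rows and cell
columns, blacklists as 3-column BED, and run manifests as JSON.  All
coordinates are 0-based half-open and round-trip without drift.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StructuralError
from .grid import BinGrid
from .rtcore import MISSING, REPLICATED, UNREPLICATED

__all__ = [
    "read_bincounts",
    "write_bincounts",
    "read_bed",
    "read_matrix",
    "write_matrix",
    "write_states_bed",
    "write_states_bedgraph",
    "write_bedgraph",
    "write_manifest",
    "read_manifest",
]

_STATE_NAME = {MISSING: "missing", UNREPLICATED: "unreplicated", REPLICATED: "replicated"}


def read_bincounts(path) -> tuple[BinGrid, np.ndarray]:
    """Read a 4-column bin-count TSV (chrom, start, end, count).

    Validates the grid (sorted, non-overlapping, constant width) and the
    counts (non-negative integers), reporting the first offending line.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "count"],
        comment="#",
    )
    counts = df["count"]
    bad = counts.isna() | (counts != counts.astype("int64", errors="ignore"))
    frac = counts.to_numpy(dtype=float) % 1 != 0
    if frac.any():
        line = int(np.argmax(frac)) + 1
        raise StructuralError(f"{path}: non-integer count at line {line}")
    neg = counts.to_numpy(dtype=float) < 0
    if neg.any():
        line = int(np.argmax(neg)) + 1
        raise StructuralError(f"{path}: negative count at line {line}")
    try:
        grid = BinGrid(df[["chrom", "start", "end"]])
    except StructuralError as exc:
        raise StructuralError(f"{path}: {exc}") from exc
    return grid, counts.to_numpy(dtype=np.int64)


def write_bincounts(path, grid: BinGrid, counts: np.ndarray) -> None:
    df = grid.to_frame()
    df["count"] = np.asarray(counts, dtype=np.int64)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """3+ column BED (e.g. a blacklist); extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def read_matrix(path) -> pd.DataFrame:
    """Feature x cell TSV matrix with a leading index column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t")


def write_states_bed(path, grid: BinGrid, states: np.ndarray, cell_id: str = ".") -> None:
    """Binarized profile as a BED9-like track with a state name column."""
    s = np.asarray(states)
    df = grid.to_frame()
    df["name"] = [_STATE_NAME[int(v)] for v in s]
    df["score"] = np.where(s == REPLICATED, 1000, np.where(s == UNREPLICATED, 0, 500))
    df["strand"] = "."
    df["thickStart"] = df["start"]
    df["thickEnd"] = df["end"]
    df["itemRgb"] = np.where(
        s == REPLICATED, "49,130,189", np.where(s == UNREPLICATED, "254,224,76", "255,255,255")
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def write_states_bedgraph(path, grid: BinGrid, states: np.ndarray) -> None:
    """IGV-loadable bedGraph with -1 (unreplicated) / +1 (replicated) coding;
    missing bins are omitted."""
    s = np.asarray(states)
    keep = s != MISSING
    df = grid.to_frame()[keep]
    df["value"] = np.where(s[keep] == REPLICATED, 1, -1)
    df.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(path, grid: BinGrid, values: np.ndarray) -> None:
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(v)
    df = grid.to_frame()[keep]
    df["value"] = v[keep]
    df.to_csv(path, sep="\t", header=False, index=False)


def write_manifest(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
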