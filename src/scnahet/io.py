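"""Readers and writers for the pipeline's on-disk formats.

Genomic text output follows BED conventions (0-based half-open); SEG
files follow the conventional 1-based inclusive dialect, converted at
the reader/writer boundary.  Matrices are TSV with bins as rows keyed by
chrom/start/end and cells as columns (a cells-as-rows dialect is
supported behind a flag of :func:`read_cn_matrix`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinScheme
from .heterogeneity import TumorCellSet


# -- bin schemes (BED) ------------------------------------------------------

def write_bin_scheme(scheme: BinScheme, path: str | Path) -> None:
    df = scheme.to_frame()
    df["bin_id"] = np.arange(scheme.n_bins)
    df[["chrom", "start", "end", "bin_id", "weight"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bin_scheme(path: str | Path) -> BinScheme:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "bin_id", "weight"])
    return BinScheme.from_frame(df)


# -- matrices (bins x cells TSV) -------------------------------------------

def write_matrix(matrix: np.ndarray, cell_ids: list[str], scheme: BinScheme,
                 path: str | Path) -> None:
    """Write a cells-x-bins matrix as a bins-as-rows TSV."""
    df = pd.DataFrame({"chrom": scheme.chrom, "start": scheme.start,
                       "end": scheme.end})
    for i, cid in enumerate(cell_ids):
        df[cid] = matrix[i]
    df.to_csv(path, sep="\t", index=False)


def read_counts_matrix(path: str | Path) -> tuple[np.ndarray, list[str], BinScheme]:
    df = pd.read_csv(path, sep="\t")
    scheme = BinScheme.from_frame(df[["chrom", "start", "end"]])
    cells = [c for c in df.columns if c not in ("chrom", "start", "end")]
    mat = df[cells].to_numpy().T
    return mat, cells, scheme


def read_cn_matrix(path: str | Path, dialect: str = "bins-as-rows",
                   strict: bool = False) -> TumorCellSet:
    """Read an integer CN matrix into a :class:`TumorCellSet`.

    In lenient mode (default) float-encoded integers (within 0.01 of an
    integer) are coerced; anything further off, or any duplicated cell ID,
    is rejected.  ``dialect`` selects bins-as-rows (chrom/start/end columns
    then one column per cell) or cells-as-rows (transposed).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        raise ValueError("duplicated cell IDs in header")
    df = pd.read_csv(path, sep="\t")
    if dialect == "cells-as-rows":
        id_col = df.columns[0]
        cells = df[id_col].astype(str).tolist()
        body = df.drop(columns=[id_col])
        bin_keys = [tuple(c.split(":")) for c in body.columns]
        bed = pd.DataFrame(
            {"chrom": [k[0] for k in bin_keys],
             "start": [int(k[1]) for k in bin_keys],
             "end": [int(k[2]) for k in bin_keys]})
        scheme = BinScheme.from_frame(bed)
        values = body.to_numpy(float)
    elif dialect == "bins-as-rows":
        scheme = BinScheme.from_frame(df[["chrom", "start", "end"]])
        cells = [c for c in df.columns if c not in ("chrom", "start", "end")]
        values = df[cells].to_numpy(float).T
    else:
        raise ValueError(f"unknown dialect: {dialect}")

    if len(set(cells)) != len(cells):
        raise ValueError("duplicated cell IDs")
    rounded = np.round(values)
    off = np.abs(values - rounded)
    if np.any(off > 0.01):
        raise ValueError("non-integer copy number entries")
    if strict and np.any(off > 0):
        raise ValueError("float-encoded entries rejected in strict mode")
    return TumorCellSet(rounded.astype(int), cells, scheme)


def write_cn_matrix(cells: TumorCellSet, path: str | Path) -> None:
    write_matrix(cells.matrix, cells.cell_ids, cells.scheme, path)


# -- SEG (1-based inclusive) ------------------------------------------------

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark",
               "seg.mean", "integer_cn"]


def write_seg(segments: pd.DataFrame, scheme: BinScheme, cell_id: str,
              cn: np.ndarray, path: str | Path, mode: str = "w") -> None:
    """Write a per-cell segment table (bin-indexed, half-open) as SEG."""
    rows = []
    for _, seg in segments.iterrows():
        a, b = int(seg["start"]), int(seg["end"])
        rows.append({
            "ID": cell_id,
            "chrom": scheme.chrom[a],
            "loc.start": int(scheme.start[a]) + 1,     # to 1-based inclusive
            "loc.end": int(scheme.end[b - 1]),
            "num.mark": b - a,
            "seg.mean": float(seg["mean"]),
            "integer_cn": int(cn[a]),
        })
    header = mode == "w"
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(
        path, sep="\t", index=False, mode=mode, header=header)


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG file into 0-based half-open columns chrom/start/end/cn
    (one frame for all IDs; ``ID`` column preserved)."""
    df = pd.read_csv(path, sep="\t")
    cn_col = "integer_cn" if "integer_cn" in df.columns else "seg.mean"
    return pd.DataFrame({
        "ID": df["ID"],
        "chrom": df["chrom"],
        "start": df["loc.start"].astype(np.int64) - 1,  # to 0-based half-open
        "end": df["loc.end"].astype(np.int64),
        "cn": df[cn_col].astype(float),
    })


def seg_to_bins(seg: pd.DataFrame, scheme: BinScheme) -> np.ndarray:
    """Rasterize one sample's SEG rows onto a bin scheme (nearest-integer CN)."""
    out = np.zeros(scheme.n_bins, dtype=int)
    for _, row in seg.iterrows():
        lo, hi = scheme.interval_to_bins(row["chrom"], int(row["start"]),
                                         int(row["end"]))
        out[lo:hi] = int(round(row["cn"]))
    return out


# -- JSON summaries ---------------------------------------------------------

def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True)
                          + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
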