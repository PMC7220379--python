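"""Multi-region comparison: bulk-vs-bulk differential CNAs and their
recovery as sub-clonal variation in single-cell data.

Two spatially resolved biopsies of the same tumor typically differ in
their bulk copy-number profiles; much of that inter-biopsy variation is
expected to re-appear as sub-clonal variation within one biopsy's
single-cell data (a minority of cells already carrying the other
biopsy's state).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import BinScheme
from .heterogeneity import subclonal_bin_census


@dataclass
class DifferentialAlteration:
    start: int                  # half-open global bin range
    end: int
    chrom: str
    cn_a: np.ndarray            # per-bin CN in biopsy A over the interval
    cn_b: np.ndarray
    status: str = "unscored"    # shared-in-cells | bulk-only | unscored


def diff_bulk(bulk_a: np.ndarray, bulk_b: np.ndarray, scheme: BinScheme,
              min_len: int = 5) -> list[DifferentialAlteration]:
    """Maximal runs of bins where the two bulk integer CN profiles differ,
    kept when at least ``min_len`` bins long."""
    a = np.asarray(bulk_a)
    b = np.asarray(bulk_b)
    if a.shape != b.shape or len(a) != scheme.n_bins:
        raise ValueError("bulk profiles must share the bin scheme")
    neq = a != b
    same = scheme.same_chrom_as_prev()
    out = []
    i, n = 0, len(a)
    while i < n:
        if neq[i]:
            j = i + 1
            while j < n and neq[j] and same[j]:
                j += 1
            if j - i >= min_len:
                out.append(DifferentialAlteration(
                    start=i, end=j, chrom=str(scheme.chrom[i]),
                    cn_a=a[i:j].copy(), cn_b=b[i:j].copy()))
            i = j
        else:
            i += 1
    return out


@dataclass
class RecoveryReport:
    differentials: list[DifferentialAlteration]
    recovery_rate: float
    cell_only_bins: np.ndarray   # sub-clonal bins seen only in cells


def match_in_cells(differentials: list[DifferentialAlteration],
                   matrix: np.ndarray, matrix_region: str = "A",
                   min_frac: float = 0.10,
                   overlap_frac: float = 0.5) -> RecoveryReport:
    """Score each bulk differential against one biopsy's single cells.

    A differential is shared-in-cells iff >= min_frac of cells carry the
    *other* biopsy's CN state over >= overlap_frac of the interval's bins;
    otherwise bulk-only.  Cell-only events are sub-clonal census bins not
    covered by any bulk differential.
    """
    matrix = np.asarray(matrix)
    n_cells = matrix.shape[0]
    shared = 0
    for d in differentials:
        other = d.cn_b if matrix_region.upper() == "A" else d.cn_a
        seg = matrix[:, d.start:d.end]
        match_frac = np.mean(seg == other[None, :], axis=1)
        carriers = int(np.sum(match_frac >= overlap_frac))
        if n_cells > 0 and carriers / n_cells >= min_frac - 1e-12:
            d.status = "shared-in-cells"
            shared += 1
        else:
            d.status = "bulk-only"
    rate = shared / len(differentials) if differentials else 1.0

    cell_only = np.array([], dtype=int)
    if matrix.size:
        sub = subclonal_bin_census(matrix, min_frac)
        covered = np.zeros(matrix.shape[1], dtype=bool)
        for d in differentials:
            covered[d.start:d.end] = True
        cell_only = np.flatnonzero(sub & ~covered)
    return RecoveryReport(differentials=differentials, recovery_rate=rate,
                          cell_only_bins=cell_only)
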