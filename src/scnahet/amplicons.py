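"""Focal amplification and homozygous-deletion analysis.

An amplicon is a maximal run of contiguous bins with copy number strictly
above a threshold (default 5) that stays focal (default <= ~10 Mb); longer
runs are broad gains, not amplicons.  Across a tumor's cells the module
quantifies amplicon mosaicism (presence in one sub-population, absence in
another), dosage strata (e.g. <30 vs >=30 copies at the same locus), and
mutual exclusivity of amplicon pairs by a one-sided Fisher exact test
(alternative: odds ratio < 1, i.e. under-co-occurrence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .genome import BinScheme

DEFAULT_CN_THRESHOLD = 5       # "copy number higher than 5", exclusive
DEFAULT_MAX_SPAN = 17          # bins; ~10 Mb at 600 kb resolution
DEFAULT_DEL_MAX_SPAN = 5


@dataclass
class AmpliconScan:
    amplicons: list[tuple[int, int]]   # focal runs, half-open bin ranges
    broad_gains: list[tuple[int, int]]  # runs above threshold but too long


def _threshold_runs(cn: np.ndarray, scheme: BinScheme,
                    above: bool, threshold: int) -> list[tuple[int, int]]:
    flag = (cn > threshold) if above else (cn == threshold)
    same = scheme.same_chrom_as_prev()
    runs = []
    i, n = 0, len(cn)
    while i < n:
        if flag[i]:
            j = i + 1
            while j < n and flag[j] and same[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def detect_focal_amplicons(cn: np.ndarray, scheme: BinScheme,
                           cn_threshold: int = DEFAULT_CN_THRESHOLD,
                           max_span: int = DEFAULT_MAX_SPAN) -> AmpliconScan:
    """Maximal runs of bins with CN > cn_threshold, split into focal
    amplicons (span <= max_span) and broad gains."""
    runs = _threshold_runs(np.asarray(cn), scheme, above=True,
                           threshold=cn_threshold)
    amp = [(a, b) for a, b in runs if b - a <= max_span]
    broad = [(a, b) for a, b in runs if b - a > max_span]
    return AmpliconScan(amplicons=amp, broad_gains=broad)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for a, b in ordered[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


@dataclass
class AmpliconMatrix:
    intervals: list[tuple[int, int]]   # merged across cells
    presence: np.ndarray               # cells x amplicons, bool
    max_cn: np.ndarray                 # cells x amplicons, int


def amplicon_presence_matrix(matrix: np.ndarray, scheme: BinScheme,
                             cn_threshold: int = DEFAULT_CN_THRESHOLD,
                             max_span: int = DEFAULT_MAX_SPAN) -> AmpliconMatrix:
    """Union of per-cell amplicon intervals, evaluated in every cell.

    Overlapping intervals from different cells are merged; per cell,
    presence is the cell's maximum CN within the merged interval exceeding
    the same threshold.
    """
    matrix = np.asarray(matrix)
    per_cell = [detect_focal_amplicons(matrix[i], scheme, cn_threshold,
                                       max_span).amplicons
                for i in range(matrix.shape[0])]
    merged = _merge_intervals([iv for cell in per_cell for iv in cell])
    if not merged:
        return AmpliconMatrix([], np.zeros((matrix.shape[0], 0), bool),
                              np.zeros((matrix.shape[0], 0), int))
    max_cn = np.stack([matrix[:, a:b].max(axis=1) for a, b in merged], axis=1)
    return AmpliconMatrix(intervals=merged, presence=max_cn > cn_threshold,
                          max_cn=max_cn)


def detect_mosaicism(presence: np.ndarray,
                     min_frac: float = 0.10) -> tuple[np.ndarray, bool]:
    """Per-amplicon mosaic flags and the per-tumor flag.

    An amplicon is mosaic iff it is present in >= min_frac and absent in
    >= min_frac of cancer cells; the tumor is mosaic iff any amplicon is.
    """
    presence = np.asarray(presence, dtype=bool)
    if presence.size == 0:
        return np.zeros(presence.shape[1] if presence.ndim == 2 else 0,
                        dtype=bool), False
    frac = presence.mean(axis=0)
    thr = min_frac - 1e-12
    flags = (frac >= thr) & ((1.0 - frac) >= thr)
    return flags, bool(flags.any())


@dataclass
class ExclusivityResult:
    table: tuple[int, int, int, int]   # (A&B, A&!B, !A&B, !A&!B)
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    flagged: bool = False


def mutual_exclusivity_test(presence_a: np.ndarray, presence_b: np.ndarray,
                            confidence: float = 0.95) -> ExclusivityResult:
    """One-sided Fisher exact test for under-co-occurrence of two amplicons.

    p is the hypergeometric lower tail (alternative: true odds ratio < 1);
    the odds ratio is the conditional MLE with an exact confidence
    interval.  A zero margin makes the odds ratio undefined: p = 1, OR
    reported as NaN, flagged.
    """
    a = np.asarray(presence_a, dtype=bool)
    b = np.asarray(presence_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("presence vectors must cover the same cells")
    t11 = int(np.sum(a & b))
    t10 = int(np.sum(a & ~b))
    t01 = int(np.sum(~a & b))
    t00 = int(np.sum(~a & ~b))
    table = np.array([[t11, t10], [t01, t00]])
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        return ExclusivityResult((t11, t10, t01, t00), 1.0, float("nan"),
                                 float("nan"), float("nan"), flagged=True)
    _, p = stats.fisher_exact(table, alternative="less")
    res = _odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=confidence)
    return ExclusivityResult((t11, t10, t01, t00), float(p),
                             float(res.statistic), float(ci.low),
                             float(ci.high))


@dataclass
class DosageStrata:
    strata: np.ndarray          # per amplified cell: stratum index
    breaks: tuple[float, ...]
    heterogeneous: bool


def dosage_strata(max_cn: np.ndarray, breaks: tuple[float, ...] = (30.0,),
                  cn_threshold: int = DEFAULT_CN_THRESHOLD,
                  min_frac: float = 0.10) -> DosageStrata:
    """Bin amplified cells by amplification level.

    Cells with max CN > cn_threshold are stratified at ``breaks`` (default
    a single break at 30 copies: low <= 30 < high); the locus is
    dosage-heterogeneous iff >= 2 strata each hold >= min_frac of the
    amplified cells.
    """
    max_cn = np.asarray(max_cn, dtype=float)
    amplified = max_cn > cn_threshold
    strata = np.full(len(max_cn), -1, dtype=int)
    strata[amplified] = np.searchsorted(np.asarray(breaks), max_cn[amplified],
                                        side="left")
    n_amp = int(amplified.sum())
    het = False
    if n_amp > 0:
        _, counts = np.unique(strata[amplified], return_counts=True)
        het = bool(np.sum(counts / n_amp >= min_frac - 1e-12) >= 2)
    return DosageStrata(strata=strata, breaks=tuple(breaks), heterogeneous=het)


def detect_homozygous_deletions(cn: np.ndarray, scheme: BinScheme,
                                max_span: int = DEFAULT_DEL_MAX_SPAN,
                                exclude_mask: np.ndarray | None = None,
                                ) -> list[tuple[int, int]]:
    """Maximal CN-0 runs of width <= max_span, outside excluded bins
    (registered immune receptor loci)."""
    runs = _threshold_runs(np.asarray(cn), scheme, above=False, threshold=0)
    out = []
    for a, b in runs:
        if b - a > max_span:
            continue
        if exclude_mask is not None and np.any(exclude_mask[a:b]):
            continue
        out.append((a, b))
    return out
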