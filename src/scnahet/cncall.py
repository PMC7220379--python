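"""Per-cell copy-number calling: normalization, segmentation, quantization.

A cell's journey: raw bin counts -> weight-normalized ratio (mean 1) ->
CBS segment table -> integer copy number via a least-squares multiplier.
The multiplier m* minimizes the length-weighted squared distance of
``segment_mean * m`` to the nearest integers over a configurable grid;
its optimum defines the cell's ploidy.  Flat (stromal) genomes make the
fit ill-posed (every integer multiplier fits): such cells are declared
diploid and flagged rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinScheme
from .segment import segment_profile

DEFAULT_GRID = (1.5, 6.0, 0.05)

#: Minimum spread of segment means below which quantization is ill-posed.
FLAT_TOL = 0.12

#: Mean reads/bin above which a zero-count bin is conclusive evidence of CN 0.
ZERO_RESCUE_MIN_DEPTH = 100.0
ZERO_RESCUE_RATIO = 0.1


@dataclass
class CellProfile:
    """One nucleus's counts, ratio, segments and integer copy number."""

    cell_id: str
    counts: np.ndarray
    ratio: np.ndarray
    segments: pd.DataFrame
    cn: np.ndarray
    multiplier: float | None
    quant_error: float
    total_reads: int
    flat: bool = False
    flags: list[str] = field(default_factory=list)


def normalize_counts(counts: np.ndarray, scheme: BinScheme | None = None,
                     weights: np.ndarray | None = None) -> np.ndarray:
    """Weight-normalized count ratio with mean exactly 1.

    ratio_i = (count_i / w_i) / mean_j(count_j / w_j).  Weights default to
    the scheme's expected-count weights (bin-width proportional unless a
    flat-cell reference was folded in via ``estimate_bin_weights``).
    """
    counts = np.asarray(counts, dtype=float)
    if weights is None:
        if scheme is None:
            raise ValueError("either a scheme or explicit weights is required")
        weights = scheme.weight
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be > 0")
    if counts.shape != weights.shape:
        raise ValueError("counts/weights length mismatch")
    if not np.any(counts > 0):
        raise ValueError("all-zero counts cannot be normalized")
    adj = counts / weights
    return adj / adj.mean()


def estimate_bin_weights(flat_counts: np.ndarray) -> np.ndarray:
    """Expected-count weights from a pool of flat (diploid stromal) cells.

    ``flat_counts`` is cells x bins; the pooled per-bin count, scaled to
    mean 1, estimates the mappability/GC-driven expected count per bin.
    Zero-coverage bins get the minimum positive weight observed.
    """
    pooled = np.asarray(flat_counts, dtype=float).sum(axis=0)
    if not np.any(pooled > 0):
        raise ValueError("flat reference has no reads")
    w = pooled / pooled.mean()
    positive = w[w > 0]
    w[w == 0] = positive.min()
    return w


def quantize_profile(segments: pd.DataFrame,
                     grid: tuple[float, float, float] = DEFAULT_GRID,
                     ploidy_hint: float | None = None,
                     n_bins: int | None = None,
                     min_fit_len: int = 5,
                     ) -> tuple[np.ndarray, float | None, float, bool]:
    """Integer CN per bin via the least-squares ploidy multiplier.

    Returns (cn, multiplier, error, flat).  ``error`` is the length-weighted
    mean squared distance of ``mean * m`` to the nearest integers over the
    segments used for fitting.  Exact ties on the grid break toward the
    multiplier closest to ``ploidy_hint`` (flow-sort ploidy) when given,
    else toward the smallest tied value.

    Only segments of at least ``min_fit_len`` bins enter the fit (all
    segments do when none are long enough): short segments produced by
    changepoint jitter straddle two true states, sit at half-integer copy
    numbers, and systematically pull the fit toward the doubled-ploidy
    harmonic.  All segments, short or long, still receive a rounded CN.
    """
    all_means = segments["mean"].to_numpy(float)
    all_lengths = (segments["end"] - segments["start"]).to_numpy(float)
    if n_bins is None:
        n_bins = int(segments["end"].max())
    cn = np.empty(n_bins, dtype=int)

    fit = all_lengths >= min_fit_len
    if not fit.any():
        fit = np.ones_like(fit)
    means = all_means[fit]
    lengths = all_lengths[fit]

    if means.max() - means.min() < FLAT_TOL:
        # ill-posed fit: declare diploid; short excluded segments (focal
        # deletions/amplifications) still get their diploid-scaled CN
        seg_cn = np.maximum(np.round(all_means * 2.0).astype(int), 0)
        for (a, b), c in zip(segments[["start", "end"]].to_numpy(int), seg_cn):
            cn[a:b] = c
        return cn, None, 0.0, True

    lo, hi, step = grid
    m_grid = np.arange(lo, hi + step / 2, step)
    scaled = means[None, :] * m_grid[:, None]
    resid = scaled - np.round(scaled)
    err = (resid * resid * lengths[None, :]).sum(axis=1) / lengths.sum()

    best = err.min()
    tied = np.flatnonzero(err <= best + 1e-12)
    if ploidy_hint is not None and len(tied) > 1:
        pick = tied[int(np.argmin(np.abs(m_grid[tied] - ploidy_hint)))]
    else:
        pick = tied[0]
    m_star = float(m_grid[pick])

    seg_cn = np.maximum(np.round(all_means * m_star).astype(int), 0)
    for (a, b), c in zip(segments[["start", "end"]].to_numpy(int), seg_cn):
        cn[a:b] = c
    return cn, m_star, float(err[pick]), False


def downsample_counts(counts: np.ndarray, target: int,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw exactly ``target`` reads from the cell without replacement.

    Multivariate hypergeometric over bins; deterministic under a seed.
    """
    counts = np.asarray(counts)
    total = int(counts.sum())
    if target > total:
        raise ValueError(f"cannot down-sample {total} reads to {target}")
    if target == total:
        return counts.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), target,
                                           method="marginals")


def flat_like(counts: np.ndarray, scheme: BinScheme,
              tol: float = 0.10) -> bool:
    """Cheap pre-segmentation screen for copy-number-neutral cells.

    A cell is flat-like when every chromosome's mean normalized ratio sits
    within ``tol`` of 1: whole-arm or chromosome-scale CNAs shift those
    means well beyond the tolerance, while focal V(D)J deletions do not.
    Used to pick reference cells for bin-weight calibration.
    """
    ratio = normalize_counts(counts, scheme)
    for chrom in scheme.chromosomes:
        if abs(float(ratio[scheme.chrom_slice(chrom)].mean()) - 1.0) > tol:
            return False
    return True


def calibrate_bin_weights(counts: np.ndarray, scheme: BinScheme,
                          min_flat_cells: int = 3,
                          exclude_mask: np.ndarray | None = None,
                          ) -> np.ndarray | None:
    """Mappability-like expected-count weights from a sample's flat cells.

    Pools the reads of flat-like cells (stromal/immune nuclei, the
    sample's internal diploid reference) and returns per-bin weights with
    mean 1, or None when too few flat cells are present to calibrate.

    The immune receptor loci are excluded by default: lymphocytes among
    the reference cells are somatically deleted there (V(D)J
    recombination), so pooled coverage under-estimates those bins; the
    excluded bins keep their width-proportional weight.
    """
    flat_rows = [row for row in np.asarray(counts)
                 if flat_like(row, scheme)]
    if len(flat_rows) < min_flat_cells:
        return None
    if exclude_mask is None:
        from .immune import LocusRegistry
        exclude_mask = LocusRegistry().all_bins(scheme)
    # pooled flat-cell counts carry both bin width and mappability effects,
    # so they are the complete expected-count weight
    w = estimate_bin_weights(np.vstack(flat_rows))
    w[exclude_mask] = scheme.weight[exclude_mask] * \
        (w[~exclude_mask] / scheme.weight[~exclude_mask]).mean()
    return w / w.mean()


def qc_cell(counts: np.ndarray, min_reads: int = 50_000,
            max_zero_frac: float = 0.20) -> tuple[bool, str]:
    """Cell-level QC: enough assigned reads, not too many empty bins."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if total < min_reads:
        return False, f"low_reads:{total}"
    zero_frac = float(np.mean(counts == 0))
    if zero_frac > max_zero_frac:
        return False, f"zero_bins:{zero_frac:.3f}"
    return True, "pass"


def call_cell(counts: np.ndarray, scheme: BinScheme, cell_id: str = "cell",
              alpha: float = 0.01, min_width: int = 2,
              grid: tuple[float, float, float] = DEFAULT_GRID,
              ploidy_hint: float | None = None,
              weights: np.ndarray | None = None,
              seed: int = 0) -> CellProfile:
    """Full per-cell pipeline: normalize -> segment -> quantize.

    After quantization, isolated zero-count bins inside non-zero segments
    are rescued to CN 0 when the mean depth makes a zero count conclusive
    (focal homozygous deletions narrower than the segmentation minimum
    width, e.g. 1-bin V(D)J deletions, would otherwise be smoothed away).
    """
    counts = np.asarray(counts)
    ratio = normalize_counts(counts, scheme, weights=weights)
    segments = segment_profile(ratio, alpha=alpha, min_width=min_width,
                               scheme=scheme, seed=seed)
    cn, mult, err, flat = quantize_profile(segments, grid=grid,
                                           ploidy_hint=ploidy_hint,
                                           n_bins=scheme.n_bins)
    flags = ["flat"] if flat else []
    depth = counts.sum() / scheme.n_bins
    if depth >= ZERO_RESCUE_MIN_DEPTH:
        rescue = (ratio <= ZERO_RESCUE_RATIO) & (cn >= 1)
        if np.any(rescue):
            cn = cn.copy()
            cn[rescue] = 0
            flags.append("zero_rescue")
    return CellProfile(cell_id=cell_id, counts=counts, ratio=ratio,
                       segments=segments, cn=cn, multiplier=mult,
                       quant_error=err, total_reads=int(counts.sum()),
                       flat=flat, flags=flags)
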