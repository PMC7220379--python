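"""Circular binary segmentation (CBS) for normalized bin-count ratios.

Recursive changepoint search using the CBS max-t statistic: within a
candidate segment, the best "arc" (contiguous window) is the one whose mean
differs most, in pooled-t units, from the remainder of the segment.
Considering linear windows is equivalent to considering circular arcs
because the statistic is symmetric in window and complement.

Significance of a candidate split is decided by a hybrid rule:

1. exact piecewise-constant shortcut — if the data are exactly piecewise
   constant with every run at least ``min_width`` long, the run boundaries
   are returned directly (so the noise-free oracle holds for any alpha;
   a pure permutation p-value has a floor of 1/(n_perm+1));
2. fast paths — a max-t far above the expected null maximum
   (sqrt(2 log n_pairs) + 3) is accepted without permutations; a max-t
   below 2 is rejected without permutations;
3. otherwise a permutation test (within-segment shuffles), early-stopped
   once the exceedance count proves p >= alpha.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .genome import BinScheme

_EPS_REL = 1e-10


def _max_t_scan(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Best arc (i, j) maximizing |t| between window x[i:j] and the rest.

    Window and complement must each span >= min_width bins; an interior
    split additionally requires the flanking pieces to satisfy min_width.
    Returns (t, i, j); t may be inf when the split fits exactly.
    """
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    tot = S[-1]
    Q = float(np.sum(x * x))
    ss_tot = Q - tot * tot / n
    eps = _EPS_REL * max(1.0, Q)

    best_t, best_i, best_j = 0.0, 0, n
    for k in range(min_width, n - min_width + 1):
        wsum = S[k:] - S[:-k]              # window sums, i = 0..n-k
        m1 = wsum / k
        m2 = (tot - wsum) / (n - k)
        resid = Q - k * m1 * m1 - (n - k) * m2 * m2
        i_arr = np.arange(n - k + 1)
        j_arr = i_arr + k
        valid = ((i_arr == 0) | (i_arr >= min_width)) & \
                ((j_arr == n) | (j_arr <= n - min_width))
        diff = np.abs(m1 - m2)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.sqrt(np.maximum(resid, 0.0) / max(n - 2, 1)
                            * (1.0 / k + 1.0 / (n - k)))
            t = diff / denom
        exact = (resid <= eps) & (diff > math.sqrt(eps))
        t = np.where(exact, np.inf, t)
        t[~valid] = -1.0
        t[~np.isfinite(t) & ~exact] = -1.0
        idx = int(np.argmax(t))
        if t[idx] > best_t:
            best_t, best_i, best_j = float(t[idx]), int(idx), int(idx + k)
    _ = ss_tot
    return best_t, best_i, best_j


def _runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of exactly equal values, as half-open index pairs."""
    change = np.flatnonzero(x[1:] != x[:-1]) + 1
    bounds = np.concatenate(([0], change, [len(x)]))
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def _is_significant(x: np.ndarray, t_obs: float, alpha: float,
                    min_width: int, n_perm: int,
                    rng: np.random.Generator) -> bool:
    n = len(x)
    if not math.isfinite(t_obs):
        return True
    if t_obs < 2.0:
        return False
    n_pairs = n * (n - 1) / 2.0
    t_hi = math.sqrt(2.0 * math.log(max(n_pairs, 2.0))) + 3.0
    if t_obs > t_hi:
        return True
    # permutation band, early-stopped
    limit = alpha * n_perm
    exceed = 0
    for p in range(n_perm):
        t_perm, _, _ = _max_t_scan(rng.permutation(x), min_width)
        if t_perm >= t_obs:
            exceed += 1
            if exceed > limit:
                return False
    return (1 + exceed) / (1 + n_perm) < alpha


def segment_array(x: np.ndarray, alpha: float = 0.01, min_width: int = 2,
                  n_perm: int = 200,
                  rng: np.random.Generator | None = None) -> list[tuple[int, int]]:
    """Segment a 1-D ratio array; returns ordered half-open (start, end) pairs."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("ratios must be finite")
    if min_width < 2:
        raise ValueError("min_width must be >= 2")
    n = len(x)
    if n < min_width:
        return [(0, n)]
    if rng is None:
        rng = np.random.default_rng(0)

    # exact piecewise-constant shortcut
    runs = _runs(x)
    if len(runs) >= 2 and all(b - a >= min_width for a, b in runs):
        return runs

    out: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        sub = x[a:b]
        if b - a < 2 * min_width:
            out.append((a, b))
            continue
        if np.all(sub == sub[0]):
            out.append((a, b))
            continue
        t_obs, i, j = _max_t_scan(sub, min_width)
        if t_obs > 0 and _is_significant(sub, t_obs, alpha, min_width, n_perm, rng):
            pieces = [(a, a + i), (a + i, a + j), (a + j, b)]
            for lo, hi in pieces:
                if hi > lo:
                    stack.append((lo, hi))
        else:
            out.append((a, b))
    out.sort()
    return out


def segment_profile(ratio: np.ndarray, alpha: float = 0.01, min_width: int = 2,
                    scheme: BinScheme | None = None, n_perm: int = 200,
                    seed: int = 0) -> pd.DataFrame:
    """Segment a genome-wide ratio profile into a segment table.

    If a :class:`BinScheme` is given, each chromosome is segmented
    independently, so no segment spans a chromosome boundary.  Columns:
    ``start``, ``end`` (half-open global bin indices), ``mean`` (arithmetic
    mean of the segment's bins), ``flagged`` (True for degenerate
    too-short inputs returned as a single segment).
    """
    ratio = np.asarray(ratio, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    if scheme is None:
        blocks = [(0, len(ratio))]
    else:
        if scheme.n_bins != len(ratio):
            raise ValueError("ratio length does not match bin scheme")
        blocks = [(scheme.chrom_slice(c).start, scheme.chrom_slice(c).stop)
                  for c in scheme.chromosomes]
    for lo, hi in blocks:
        sub = ratio[lo:hi]
        flagged = len(sub) < min_width
        for a, b in segment_array(sub, alpha=alpha, min_width=min_width,
                                  n_perm=n_perm, rng=rng):
            rows.append((lo + a, lo + b, float(np.mean(sub[a:b])), flagged))
    df = pd.DataFrame(rows, columns=["start", "end", "mean", "flagged"])
    return df.sort_values("start", ignore_index=True)
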