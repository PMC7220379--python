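"""Immune-cell detection from single-nucleus copy-number profiles.

Mature T- and B-cells carry focal homozygous deletions at their receptor
loci, the scar of V(D)J recombination: TCRa (chr14) / TCRb (chr7) for
T-cells, IGH (chr14) / IGL (chr22) for B-cells.  In otherwise flat
(copy-number-neutral) diploid genomes these deletions identify the cell
type; their breakpoint bins differ between independent recombination
events, so breakpoint sharing across nuclei measures clonal expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import BinScheme

#: hg19 receptor-locus coordinates (configurable).
DEFAULT_LOCI: dict[str, tuple[str, int, int]] = {
    "TCRA": ("chr14", 22_090_000, 23_030_000),
    "TCRB": ("chr7", 141_998_000, 142_510_000),
    "IGH": ("chr14", 106_032_000, 107_288_000),
    "IGL": ("chr22", 22_380_000, 23_265_000),
}
T_CELL_LOCI: tuple[str, ...] = ("TCRA", "TCRB")
B_CELL_LOCI: tuple[str, ...] = ("IGH", "IGL")

#: Bins of slack around each locus when scanning for deletions: at ~600 kb
#: resolution a sub-megabase deletion's segmentation support smears over
#: neighbouring bins (observed spreads cover ~14 bins).
DEFAULT_PAD_BINS = 7


@dataclass
class LocusRegistry:
    """Named receptor-locus intervals, resolvable to bin ranges."""

    loci: dict[str, tuple[str, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LOCI))

    def resolve(self, scheme: BinScheme,
                pad_bins: int = DEFAULT_PAD_BINS) -> dict[str, tuple[int, int]]:
        """Half-open bin windows per locus, padded and clipped to the
        chromosome; overlapping windows on the same chromosome are split
        at the midpoint so each bin belongs to at most one locus."""
        out: dict[str, tuple[int, int]] = {}
        for name, (chrom, s, e) in self.loci.items():
            lo, hi = scheme.interval_to_bins(chrom, s, e)
            csl = scheme.chrom_slice(chrom)
            out[name] = (max(csl.start, lo - pad_bins),
                         min(csl.stop, hi + pad_bins))
        names = list(out)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                (a0, a1), (b0, b1) = out[a], out[b]
                if a0 < b1 and b0 < a1:  # overlap after padding
                    mid = (max(a0, b0) + min(a1, b1)) // 2
                    if a0 <= b0:
                        out[a], out[b] = (a0, mid), (mid, b1)
                    else:
                        out[b], out[a] = (b0, mid), (mid, a1)
        return out

    def all_bins(self, scheme: BinScheme,
                 pad_bins: int = DEFAULT_PAD_BINS) -> np.ndarray:
        mask = np.zeros(scheme.n_bins, dtype=bool)
        for lo, hi in self.resolve(scheme, pad_bins).values():
            mask[lo:hi] = True
        return mask


@dataclass
class ImmuneCall:
    """Classification of one nucleus with its supporting deletions."""

    cell_id: str
    cell_class: str  # T | B | X-loss-T | flat-stromal | pseudo-diploid | cancer
    deletions: list[tuple[str, int, int]] = field(default_factory=list)
    x_cn: float = float("nan")


def is_flat_diploid(cn: np.ndarray, scheme: BinScheme,
                    max_aberrant_frac: float = 0.02,
                    exclude: np.ndarray | None = None) -> bool:
    """True iff the fraction of autosomal bins with CN != 2 is small.

    ``exclude`` masks bins ignored by the census (e.g. immune loci, so a
    V(D)J deletion does not disqualify an otherwise flat genome).
    """
    mask = scheme.autosome_mask()
    if exclude is not None:
        mask = mask & ~exclude
    aberrant = np.mean(cn[mask] != 2) if mask.any() else 0.0
    return bool(aberrant <= max_aberrant_frac)


def _zero_runs(cn: np.ndarray, lo: int, hi: int,
               max_width: int) -> list[tuple[int, int]]:
    runs = []
    i = lo
    while i < hi:
        if cn[i] == 0:
            j = i
            while j < hi and cn[j] == 0:
                j += 1
            if j - i <= max_width:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def detect_vdj_deletions(cn: np.ndarray, scheme: BinScheme,
                         registry: LocusRegistry | None = None,
                         cell_id: str = "cell",
                         max_del_width: int = 5,
                         expected_x_cn: int = 2,
                         pad_bins: int = DEFAULT_PAD_BINS) -> ImmuneCall:
    """Classify a flat-diploid nucleus by its receptor-locus deletions.

    Scans each locus window for contiguous runs of homozygous (CN 0) bins
    of width 1..max_del_width.  A TCR deletion makes the cell a T-cell
    (X-loss-T when additionally one whole X copy is missing); an Ig
    deletion without any TCR deletion makes it a B-cell; otherwise the
    cell is flat-stromal.  Hemizygous (CN 1) dips are not evidence.
    """
    registry = registry or LocusRegistry()
    windows = registry.resolve(scheme, pad_bins)
    dels: list[tuple[str, int, int]] = []
    for name, (lo, hi) in windows.items():
        for a, b in _zero_runs(cn, lo, hi, max_del_width):
            dels.append((name, a, b))
    has_t = any(d[0] in T_CELL_LOCI for d in dels)
    has_b = any(d[0] in B_CELL_LOCI for d in dels)
    x_cn = float("nan")
    if "chrX" in scheme.chromosomes:
        xs = scheme.chrom_slice("chrX")
        x_cn = float(np.median(cn[xs]))
    if has_t:
        cls = "X-loss-T" if detect_x_loss(cn, scheme, expected_x_cn) else "T"
    elif has_b:
        cls = "B"
    else:
        cls = "flat-stromal"
        dels = []
    return ImmuneCall(cell_id=cell_id, cell_class=cls, deletions=dels, x_cn=x_cn)


def detect_x_loss(cn: np.ndarray, scheme: BinScheme,
                  expected_x_cn: int = 2) -> bool:
    """Whole-X loss: median X CN one below baseline and >=90% of X bins there."""
    if "chrX" not in scheme.chromosomes:
        return False
    xs = scheme.chrom_slice("chrX")
    x = cn[xs]
    target = expected_x_cn - 1
    return bool(np.median(x) == target and np.mean(x == target) >= 0.90)


def tcr_breakpoint_distance(del_a: tuple[int, int],
                            del_b: tuple[int, int]) -> int:
    """Bins offset between left breakpoints plus offset between right ones."""
    if del_a is None or del_b is None:
        raise ValueError("both cells must carry a deletion at the locus")
    (la, ra), (lb, rb) = del_a, del_b
    return abs(la - lb) + abs(ra - rb)


@dataclass
class ClonalityResult:
    p_value: float
    p_report: str
    hits: int
    n_perm: int
    group_size: int
    pool_size: int
    observed_identical: bool


def clonality_permutation_test(group: list[tuple[int, int]],
                               pool: list[tuple[int, int]],
                               n_perm: int = 1_000_000,
                               seed: int = 0) -> ClonalityResult:
    """How unusual is a set of nuclei all sharing identical breakpoints?

    Sets of ``len(group)`` nuclei are sampled from the reference pool
    (without replacement), ``n_perm`` times; the statistic is the
    indicator that every sampled nucleus carries identical breakpoint
    bins.  p = (1 + hits) / (1 + n_perm), reported as "<1/n_perm" when no
    sampled set is uniform.
    """
    g = len(group)
    if g < 2:
        raise ValueError("group of 1: clonality statistic is degenerate")
    if len(pool) < g:
        raise ValueError("pool smaller than group")
    rng = np.random.default_rng(seed)
    # map breakpoint pairs to integer codes
    code_of: dict[tuple[int, int], int] = {}
    codes = np.array([code_of.setdefault(tuple(bp), len(code_of))
                      for bp in pool], dtype=np.int64)
    n = len(codes)
    hits = 0
    chunk = max(1, min(n_perm, 200_000 // max(n, 1) * 64))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, g - 1, axis=1)[:, :g]
        sampled = codes[idx]
        hits += int(np.sum(np.all(sampled == sampled[:, :1], axis=1)))
        done += m
    p = (1 + hits) / (1 + n_perm)
    report = f"<{1.0 / n_perm:g}" if hits == 0 else f"{p:g}"
    obs_codes = {tuple(bp) for bp in group}
    return ClonalityResult(p_value=p, p_report=report, hits=hits,
                           n_perm=n_perm, group_size=g, pool_size=n,
                           observed_identical=len(obs_codes) == 1)


def detection_sensitivity(calls: list[ImmuneCall], expected_class: str) -> float:
    """Fraction of a purified population receiving its expected label."""
    if not calls:
        raise ValueError("empty input")
    return float(np.mean([c.cell_class == expected_class for c in calls]))


def classify_pseudo_diploid(cn: np.ndarray, scheme: BinScheme,
                            clonal_pins: np.ndarray | None,
                            registry: LocusRegistry | None = None,
                            window: int = 3,
                            max_shared_frac: float = 0.20,
                            min_aberrant_frac: float = 0.02) -> str:
    """Aberrant 2N-gate nucleus: tumor lineage or private pseudo-diploid?

    Pseudo-diploid iff the cell is non-flat, carries no immune-locus
    deletion, and matches fewer than ``max_shared_frac`` of the tumor's
    clonal breakpoint pins (within the pin equivalence window).  Returns
    one of "cancer", "pseudo-diploid", "flat", "immune",
    "aberrant-unassigned" (no tumor signature available).
    """
    registry = registry or LocusRegistry()
    locus_mask = registry.all_bins(scheme)
    if is_flat_diploid(cn, scheme, min_aberrant_frac, exclude=locus_mask):
        return "flat"
    call = detect_vdj_deletions(cn, scheme, registry)
    if call.deletions:
        return "immune"
    if clonal_pins is None or len(clonal_pins) == 0:
        return "aberrant-unassigned"
    from .heterogeneity import call_breakpoints
    bps = call_breakpoints(cn, scheme)
    half = window // 2
    shared = sum(1 for pin in clonal_pins
                 if len(bps) and np.min(np.abs(bps - pin)) <= half)
    frac = shared / len(clonal_pins)
    return "pseudo-diploid" if frac < max_shared_frac else "cancer"


def expected_unique_breakpoint_prob(n_cells: int, span: int,
                                    widths: tuple[int, int] = (1, 3)) -> float:
    """Probability that no two of n independent recombination events share
    identical (left, right) breakpoints, under uniform placement of a
    deletion of uniform width over a span of bins (birthday problem)."""
    n_pairs = sum(span - w + 1 for w in range(widths[0], widths[1] + 1))
    if n_cells > n_pairs:
        return 0.0
    log_p = sum(math.log1p(-k / n_pairs) for k in range(n_cells))
    return math.exp(log_p)
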