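"""Intra-tumoral copy-number heterogeneity statistics.

Across a tumor's cancer nuclei (cells x bins integer CN): the per-bin
clonal/sub-clonal census and % genome sub-clonal, recurrent breakpoint
"pins" with clonal/sub-clonal/rare labels, hierarchical clone clustering,
clonal-composition classes, and association tests against clinical
covariates.

Threshold semantics follow the census/pin rules exactly: the census
requires each state in *at least* 10% of nuclei (inclusive); a pin is
clonal when carried by *over* 90% of nuclei (exclusive) and rare when
carried by at most 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .genome import BinScheme


@dataclass
class TumorCellSet:
    """Cells x bins integer CN matrix with per-cell metadata."""

    matrix: np.ndarray
    cell_ids: list[str]
    scheme: BinScheme
    metadata: pd.DataFrame | None = None  # indexed by cell id

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be cells x bins")
        if self.matrix.shape[1] != self.scheme.n_bins:
            raise ValueError("matrix width does not match bin scheme")
        if self.matrix.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length mismatch")
        if np.any(self.matrix < 0):
            raise ValueError("copy numbers must be >= 0")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicated cell IDs")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def subset(self, mask: np.ndarray) -> "TumorCellSet":
        ids = [c for c, m in zip(self.cell_ids, mask) if m]
        meta = self.metadata.loc[ids] if self.metadata is not None else None
        return TumorCellSet(self.matrix[mask], ids, self.scheme, meta)


# ---------------------------------------------------------------------------
# per-bin census
# ---------------------------------------------------------------------------

def subclonal_bin_census(matrix: np.ndarray, min_frac: float = 0.10) -> np.ndarray:
    """Per-bin flag: True where the bin is sub-clonal.

    A bin is sub-clonal iff at least two distinct copy-number states are
    each carried by >= min_frac of cells (boundary inclusive).
    """
    matrix = np.asarray(matrix)
    if matrix.size == 0:
        raise ValueError("empty matrix")
    n_cells, n_bins = matrix.shape
    if n_cells < 10:
        import warnings
        warnings.warn(f"census on only {n_cells} cells", stacklevel=2)
    thr = min_frac * n_cells - 1e-9  # inclusive boundary
    out = np.zeros(n_bins, dtype=bool)
    for j in range(n_bins):
        _, counts = np.unique(matrix[:, j], return_counts=True)
        out[j] = np.sum(counts >= thr) >= 2
    return out


def fraction_genome_subclonal(matrix: np.ndarray, min_frac: float = 0.10) -> float:
    """% of bins called sub-clonal by the census; in [0, 100]."""
    flags = subclonal_bin_census(matrix, min_frac)
    return 100.0 * float(np.mean(flags))


# ---------------------------------------------------------------------------
# breakpoints and pins
# ---------------------------------------------------------------------------

def call_breakpoints(cn: np.ndarray, scheme: BinScheme | None = None) -> np.ndarray:
    """Bin positions where the integer CN profile changes state.

    A change between bins i-1 and i is reported at i (the left bin of the
    new state).  Changes across chromosome boundaries are never counted.
    """
    cn = np.asarray(cn)
    change = np.zeros(len(cn), dtype=bool)
    change[1:] = cn[1:] != cn[:-1]
    if scheme is not None:
        change &= scheme.same_chrom_as_prev()
    return np.flatnonzero(change)


@dataclass
class PinSet:
    """Recurrent breakpoint pins with supporting fractions and labels."""

    pins: pd.DataFrame  # columns: bin, fraction, n_cells, label
    window: int
    low: float = 0.10
    high: float = 0.90

    def bins(self, label: str | None = None) -> np.ndarray:
        df = self.pins if label is None else self.pins[self.pins.label == label]
        return df["bin"].to_numpy(int)

    def count(self, label: str) -> int:
        return int((self.pins.label == label).sum())


def derive_pins(breakpoint_lists: list[np.ndarray], n_cells: int | None = None,
                window: int = 3, low: float = 0.10,
                high: float = 0.90) -> PinSet:
    """Merge per-cell breakpoints into recurrent pins and label them.

    Breakpoints within a ``window``-bin equivalence window are treated as
    the same pin; the pin anchor is the modal breakpoint bin (ties to the
    leftmost).  The supporting fraction is the share of cells carrying any
    breakpoint inside the window.  Labels: clonal if fraction > high, rare
    if fraction <= low, sub-clonal otherwise.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if n_cells is None:
        n_cells = len(breakpoint_lists)
    if n_cells < 2:
        raise ValueError("pins need >= 2 cells")

    # (cell, bin) pairs still unassigned
    remaining: list[set[int]] = [set(map(int, b)) for b in breakpoint_lists]
    rows = []
    while True:
        hist: dict[int, int] = {}
        for bins in remaining:
            for b in bins:
                hist[b] = hist.get(b, 0) + 1
        if not hist:
            break
        # candidate windows [w, w+window): breakpoints anywhere inside one
        # window are the same pin; pick the best-supported window (ties:
        # higher peak count, leftmost)
        best_w, best_key = None, None
        for w in range(min(hist) - window + 1, max(hist) + 1):
            inside_bins = [b for b in hist if w <= b < w + window]
            if not inside_bins:
                continue
            support = sum(1 for bins in remaining
                          if any(w <= b < w + window for b in bins))
            peak = max(hist[b] for b in inside_bins)
            key = (support, peak, -w)
            if best_key is None or key > best_key:
                best_w, best_key = w, key
        # anchor = modal bin within the chosen window (leftmost tie)
        window_bins = [b for b in sorted(hist)
                       if best_w <= b < best_w + window]
        anchor = max(window_bins, key=lambda b: (hist[b], -b))
        carriers = 0
        for bins in remaining:
            inside = {b for b in bins if best_w <= b < best_w + window}
            if inside:
                carriers += 1
                bins -= inside
        frac = carriers / n_cells
        label = "clonal" if frac > high else ("rare" if frac <= low else "sub-clonal")
        rows.append((anchor, frac, carriers, label))

    df = pd.DataFrame(rows, columns=["bin", "fraction", "n_cells", "label"])
    df = df.sort_values("bin", ignore_index=True)
    return PinSet(pins=df, window=window, low=low, high=high)


# ---------------------------------------------------------------------------
# clone clustering and composition
# ---------------------------------------------------------------------------

@dataclass
class ClonalComposition:
    assignments: np.ndarray            # clone index per cell; -1 unassigned
    frequencies: dict[int, float]      # over assigned cancer cells
    composition_class: str             # homogeneous | dominant | no-dominant
    unassigned_frac: float = 0.0
    flagged: bool = False


def classify_composition(frequencies: list[float] | dict[int, float],
                         tol: float = 0.05) -> str:
    """Homogeneous (one clone, within a 5% tolerance), dominant (>50%),
    or no-dominant."""
    freqs = list(frequencies.values()) if isinstance(frequencies, dict) \
        else list(frequencies)
    if not freqs:
        raise ValueError("empty frequency vector")
    top = max(freqs)
    if top >= 1.0 - tol:
        return "homogeneous"
    if top > 0.5:
        return "dominant"
    return "no-dominant"


def cluster_clones(matrix: np.ndarray, cut: float | None = None,
                   method: str = "average",
                   min_clone_size: int | None = None) -> ClonalComposition:
    """Hierarchical clustering of cells into clones.

    Distance is L1 over integer CN profiles, average linkage by default,
    flat clusters cut at cophenetic distance ``cut`` (default
    max(5, 1% of bins)).  Clusters smaller than max(2, 5% of cells) are
    left unassigned (-1) and excluded from the clone frequencies.
    """
    matrix = np.asarray(matrix)
    n_cells, n_bins = matrix.shape
    if n_cells < 1:
        raise ValueError("empty matrix")
    if n_cells == 1:
        return ClonalComposition(np.zeros(1, int), {0: 1.0}, "homogeneous",
                                 flagged=True)
    if cut is None:
        cut = max(5.0, 0.01 * n_bins)
    if min_clone_size is None:
        min_clone_size = max(2, int(np.ceil(0.05 * n_cells)))

    d = pdist(matrix.astype(float), metric="cityblock")
    Z = linkage(d, method=method)
    raw = fcluster(Z, t=cut, criterion="distance")

    assignments = np.full(n_cells, -1, dtype=int)
    next_id = 0
    for lab in np.unique(raw):
        members = np.flatnonzero(raw == lab)
        if len(members) >= min_clone_size:
            assignments[members] = next_id
            next_id += 1
    assigned = assignments >= 0
    if not np.any(assigned):
        # no cluster meets the size floor: a single clone of everything
        assignments[:] = 0
        freqs = {0: 1.0}
        return ClonalComposition(assignments, freqs, "homogeneous",
                                 unassigned_frac=0.0, flagged=True)
    n_assigned = int(assigned.sum())
    freqs = {int(k): int(np.sum(assignments == k)) / n_assigned
             for k in range(next_id)}
    comp = classify_composition(freqs)
    return ClonalComposition(assignments, freqs, comp,
                             unassigned_frac=1.0 - n_assigned / n_cells)


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    method: str
    statistic: float
    p_value: float
    note: str = ""


def associate(values: np.ndarray, covariate: np.ndarray) -> AssociationResult:
    """Associate per-sample heterogeneity values with a covariate.

    A two-level factor gets a two-sided Wilcoxon rank-sum test; a numeric
    covariate gets a Spearman rank correlation.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate)
    if np.issubdtype(covariate.dtype, np.number) and len(np.unique(covariate)) > 2:
        rho, p = stats.spearmanr(values, covariate)
        return AssociationResult("spearman", float(rho), float(p))
    levels = np.unique(covariate)
    if len(levels) != 2:
        raise ValueError("factor covariate must have exactly 2 levels")
    a = values[covariate == levels[0]]
    b = values[covariate == levels[1]]
    if len(a) < 2 or len(b) < 2:
        return AssociationResult("wilcoxon-rank-sum", float("nan"), float("nan"),
                                 note="group with <2 samples")
    # Mann-Whitney U == the Wilcoxon rank-sum test; exact null for small
    # tie-free samples, normal approximation otherwise
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return AssociationResult("wilcoxon-rank-sum", float(stat), float(p))
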