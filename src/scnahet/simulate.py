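"""Synthetic single-nucleus sequencing data with ground truth.

Emulates sparse single-nucleus copy-number sequencing of a breast tumor
biopsy: ~5000 genomic bins (~600 kb), ~2 million reads per nucleus, a
clonal population structure in which clones differ by arm-level and focal
events (possibly at more than two dosage states), tumor-infiltrating
immune cells carrying focal homozygous V(D)J deletions with variable
breakpoints, pseudo-diploid singleton nuclei with private CNAs, and flat
stromal cells.  Read placement is multinomial over bins with probability
proportional to true copy number x expected-count weight, where weights
carry a lognormal mappability-like jitter (sigma 0.1 by default).

Everything is reproducible: identical (config, seed) gives bit-identical
counts and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .genome import BinScheme, make_bin_scheme
from .immune import LocusRegistry, T_CELL_LOCI, B_CELL_LOCI

# class labels emitted in the truth
CANCER_PREFIX = "cancer-clone-"
T_CELL = "T-cell"
B_CELL = "B-cell"
X_LOSS_T = "X-loss-T"
PSEUDO_DIPLOID = "pseudo-diploid"
FLAT_STROMAL = "flat-stromal"


@dataclass
class CNAEvent:
    """One copy-number event on a clone: an interval plus a copy delta
    or an absolute target copy number."""

    chrom: str
    start: int
    end: int
    delta: int | None = None
    target_cn: int | None = None
    name: str | None = None

    def apply(self, cn: np.ndarray, scheme: BinScheme) -> tuple[int, int]:
        lo, hi = scheme.interval_to_bins(self.chrom, self.start, self.end)
        if self.target_cn is not None:
            cn[lo:hi] = self.target_cn
        elif self.delta is not None:
            cn[lo:hi] += self.delta
        else:
            raise ValueError("event needs delta or target_cn")
        if np.any(cn[lo:hi] < 0):
            raise ValueError(f"event {self.name or ''} drives CN below 0")
        return lo, hi


@dataclass
class CloneSpec:
    """A cancer clone: identifier, parent edge, events, cell fraction of
    the whole sample, and baseline ploidy (2 or 4)."""

    clone_id: str
    fraction: float
    events: list[CNAEvent] = field(default_factory=list)
    parent: str | None = None
    ploidy: int = 2


@dataclass
class SimConfig:
    """Study conditions for one simulated biopsy.

    Defaults mirror the emulated protocol: 116 nuclei/sample, 2M reads per
    nucleus, 5000 bins; the test-scale preset (see :func:`test_scale_config`)
    uses 100k reads over 500 bins.  The stromal fraction is free (whatever
    cell count is not claimed by clones/immune/pseudo-diploid cells is
    flat-stromal).
    """

    clones: list[CloneSpec] = field(default_factory=list)
    n_cells: int = 116
    reads_per_cell: int = 2_000_000
    n_bins: int = 5000
    n_t_cells: int = 0
    n_b_cells: int = 0
    n_pseudo_diploid: int = 0
    x_loss_frac: float = 0.0
    tcrb_prob: float = 0.5
    deletion_width: tuple[int, int] = (1, 3)
    breakpoint_span: int = 14
    weight_jitter_sigma: float = 0.1
    genome_table: dict[str, int] | None = None


@dataclass
class SimTruth:
    """Ground truth for a simulated sample."""

    labels: np.ndarray                      # per-cell class label
    cn: np.ndarray                          # cells x bins true integer CN
    breakpoints: list[np.ndarray]           # per-cell true breakpoint bins
    events: list[dict]                      # event registry
    deletions: dict[int, list[tuple[str, int, int]]]  # cell -> (locus, lo, hi)
    bin_weights: np.ndarray                 # jittered expected-count weights
    seed: int


@dataclass
class SimResult:
    counts: np.ndarray                      # cells x bins read counts
    cell_ids: list[str]
    scheme: BinScheme
    truth: SimTruth


def test_scale_config(**kw) -> SimConfig:
    """Down-scaled preset for fast experiments: 500 bins, 100k reads."""
    base = dict(n_bins=500, reads_per_cell=100_000)
    base.update(kw)
    return SimConfig(**base)


def _true_breakpoints(cn: np.ndarray, scheme: BinScheme) -> np.ndarray:
    same = scheme.same_chrom_as_prev()
    change = np.zeros(len(cn), dtype=bool)
    change[1:] = cn[1:] != cn[:-1]
    return np.flatnonzero(change & same)


def _clone_cn(clone: CloneSpec, registry: dict[str, CloneSpec],
              scheme: BinScheme) -> np.ndarray:
    chain: list[CloneSpec] = []
    node: CloneSpec | None = clone
    seen = set()
    while node is not None:
        if node.clone_id in seen:
            raise ValueError("clone parent cycle")
        seen.add(node.clone_id)
        chain.append(node)
        node = registry.get(node.parent) if node.parent else None
    cn = np.full(scheme.n_bins, clone.ploidy, dtype=int)
    for anc in reversed(chain):
        for ev in anc.events:
            ev.apply(cn, scheme)
    return cn


def simulate_sample(config: SimConfig, seed: int) -> SimResult:
    """Simulate one biopsy's bin-count matrix plus ground truth."""
    if seed is None:
        raise ValueError("seed is mandatory")
    if config.reads_per_cell <= 0:
        raise ValueError("reads_per_cell must be > 0")
    frac_total = sum(c.fraction for c in config.clones)
    if frac_total > 1.0 + 1e-9:
        raise ValueError("clone fractions exceed 1")

    rng = np.random.default_rng(seed)
    scheme = make_bin_scheme(config.n_bins, config.genome_table)
    registry = {c.clone_id: c for c in config.clones}

    # mappability-like jitter on expected counts, hidden from the caller's
    # scheme but recoverable from flat reference cells
    jitter = rng.lognormal(mean=0.0, sigma=config.weight_jitter_sigma,
                           size=scheme.n_bins) if config.weight_jitter_sigma > 0 \
        else np.ones(scheme.n_bins)
    weights = scheme.weight * jitter
    weights /= weights.mean()

    # ---- assemble the cell roster -------------------------------------
    clone_counts = {c.clone_id: int(round(c.fraction * config.n_cells))
                    for c in config.clones}
    n_special = config.n_t_cells + config.n_b_cells + config.n_pseudo_diploid
    n_cancer = sum(clone_counts.values())
    if n_cancer + n_special > config.n_cells:
        raise ValueError("clone fractions plus immune/pseudo-diploid counts "
                         "exceed n_cells")
    n_stromal = config.n_cells - n_cancer - n_special

    clone_cn = {cid: _clone_cn(c, registry, scheme)
                for cid, c in registry.items()}

    labels: list[str] = []
    cn_rows: list[np.ndarray] = []
    deletions: dict[int, list[tuple[str, int, int]]] = {}

    # deletion breakpoints are drawn inside the same padded, de-overlapped
    # locus windows the detector scans, capped to the configured span
    locus_windows = LocusRegistry().resolve(scheme)

    def _plant_vdj(cn: np.ndarray, loci: tuple[str, ...],
                   always: tuple[str, ...]) -> list[tuple[str, int, int]]:
        dels = []
        for locus in loci:
            if locus not in always and rng.random() >= config.tcrb_prob:
                continue
            lo, hi = locus_windows[locus]
            mid = (lo + hi) // 2
            span = min(hi - lo, max(config.breakpoint_span,
                                    config.deletion_width[1]))
            span_lo = max(lo, mid - span // 2)
            span_hi = min(hi, span_lo + span)
            w = int(rng.integers(config.deletion_width[0],
                                 config.deletion_width[1] + 1))
            w = min(w, span_hi - span_lo)
            left = int(rng.integers(span_lo, span_hi - w + 1))
            cn[left:left + w] = 0
            dels.append((locus, left, left + w))
        return dels

    x_lo, x_hi = (scheme.chrom_slice("chrX").start,
                  scheme.chrom_slice("chrX").stop) if "chrX" in scheme.chromosomes \
        else (0, 0)

    for cid in registry:
        for _ in range(clone_counts[cid]):
            labels.append(CANCER_PREFIX + cid)
            cn_rows.append(clone_cn[cid].copy())

    for _ in range(config.n_t_cells):
        cn = np.full(scheme.n_bins, 2, dtype=int)
        dels = _plant_vdj(cn, T_CELL_LOCI, always=("TCRA",))
        label = T_CELL
        if config.x_loss_frac > 0 and rng.random() < config.x_loss_frac:
            cn[x_lo:x_hi] = 1
            label = X_LOSS_T
        deletions[len(labels)] = dels
        labels.append(label)
        cn_rows.append(cn)

    for _ in range(config.n_b_cells):
        cn = np.full(scheme.n_bins, 2, dtype=int)
        dels = _plant_vdj(cn, B_CELL_LOCI, always=B_CELL_LOCI)
        deletions[len(labels)] = dels
        labels.append(B_CELL)
        cn_rows.append(cn)

    # pseudo-diploids carry 1-4 private arm-scale CNAs (the prototypical
    # gains/losses reported for such nuclei span chromosome arms)
    min_len = max(3, scheme.n_bins // 33)
    max_len = max(min_len + 1, scheme.n_bins // 12)
    chrom_list = [c for c in scheme.chromosomes
                  if scheme.chrom_slice(c).stop
                  - scheme.chrom_slice(c).start >= min_len]
    for _ in range(config.n_pseudo_diploid):
        cn = np.full(scheme.n_bins, 2, dtype=int)
        n_events = min(int(rng.integers(1, 5)), len(chrom_list))
        # distinct chromosomes: private CNAs never overlap/cancel
        for ci in rng.choice(len(chrom_list), size=n_events, replace=False):
            chrom = chrom_list[int(ci)]
            csl = scheme.chrom_slice(chrom)
            length = int(rng.integers(min_len,
                                      min(max_len, csl.stop - csl.start) + 1))
            lo = int(rng.integers(csl.start, max(csl.start + 1,
                                                 csl.stop - length + 1)))
            delta = int(rng.choice([-1, 1]))
            cn[lo:lo + length] = np.maximum(cn[lo:lo + length] + delta, 0)
        labels.append(PSEUDO_DIPLOID)
        cn_rows.append(cn)

    for _ in range(n_stromal):
        labels.append(FLAT_STROMAL)
        cn_rows.append(np.full(scheme.n_bins, 2, dtype=int))

    label_arr = np.asarray(labels, dtype=object)
    cn_mat = np.vstack(cn_rows) if cn_rows else np.empty((0, scheme.n_bins), int)

    # ---- read counts ---------------------------------------------------
    counts = np.empty_like(cn_mat, dtype=np.int64)
    for i in range(cn_mat.shape[0]):
        p = cn_mat[i] * weights
        total = p.sum()
        if total <= 0:
            raise ValueError("cell with zero total copy number")
        counts[i] = rng.multinomial(config.reads_per_cell, p / total)

    # ---- event registry ------------------------------------------------
    events = []
    n_cancer_cells = max(n_cancer, 1)
    for cid, clone in registry.items():
        carriers = {cid} | {k for k in registry
                            if _descends(registry, k, cid)}
        for ev in clone.events:
            carrier_cells = sum(clone_counts[k] for k in carriers)
            frac = carrier_cells / n_cancer_cells if n_cancer else 0.0
            events.append({
                "name": ev.name or f"{cid}:{ev.chrom}:{ev.start}-{ev.end}",
                "chrom": ev.chrom, "start": ev.start, "end": ev.end,
                "bins": list(scheme.interval_to_bins(ev.chrom, ev.start, ev.end)),
                "clones": sorted(carriers),
                "cell_fraction": frac,
                "clonal": bool(abs(frac - 1.0) < 1e-9),
            })

    breakpoints = [_true_breakpoints(cn_mat[i], scheme)
                   for i in range(cn_mat.shape[0])]

    # shuffle cell order so class blocks are not positional
    order = rng.permutation(len(labels))
    truth = SimTruth(labels=label_arr[order], cn=cn_mat[order],
                     breakpoints=[breakpoints[i] for i in order],
                     events=events,
                     deletions={int(np.flatnonzero(order == k)[0]): v
                                for k, v in deletions.items()},
                     bin_weights=weights, seed=seed)
    cell_ids = [f"cell_{i:04d}" for i in range(len(labels))]
    return SimResult(counts=counts[order], cell_ids=cell_ids,
                     scheme=scheme, truth=truth)


def _descends(registry: dict[str, CloneSpec], child: str, ancestor: str) -> bool:
    node = registry[child].parent
    while node is not None:
        if node == ancestor:
            return True
        node = registry[node].parent
    return False


def simulate_bulk_pair(mixture_a: dict[str, float], mixture_b: dict[str, float],
                       clones: list[CloneSpec], scheme: BinScheme,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Bulk CN profiles of two region-specific clone mixtures.

    Bulk CN per bin is the mixture-weighted mean of clone CN, rounded to
    the nearest integer (numpy half-to-even).  Returns the two per-bin
    integer profiles and the registry of truly differential runs.
    """
    if not mixture_a or not mixture_b:
        raise ValueError("empty mixture")
    registry = {c.clone_id: c for c in clones}
    missing = (set(mixture_a) | set(mixture_b)) - set(registry)
    if missing:
        raise ValueError(f"mixtures reference unknown clones: {sorted(missing)}")
    _ = np.random.default_rng(seed)  # reserved for future noise models

    def _bulk(mix: dict[str, float]) -> np.ndarray:
        w = np.array(list(mix.values()), dtype=float)
        w = w / w.sum()
        stack = np.vstack([_clone_cn(registry[cid], registry, scheme)
                           for cid in mix])
        return np.rint(w @ stack).astype(int)

    a, b = _bulk(mixture_a), _bulk(mixture_b)
    diffs = []
    same_chrom = scheme.same_chrom_as_prev()
    neq = a != b
    i = 0
    n = scheme.n_bins
    while i < n:
        if neq[i]:
            j = i + 1
            while j < n and neq[j] and same_chrom[j]:
                j += 1
            diffs.append({"start": i, "end": j,
                          "chrom": str(scheme.chrom[i])})
            i = j
        else:
            i += 1
    return a, b, diffs
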