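"""Genome bin schemes.

A :class:`BinScheme` is an ordered partition of the genome into fixed-width
bins, the coordinate backbone for every single-cell copy-number profile in
this package.  At the default resolution of 5000 bins a human genome yields
~600 kb bins, sufficient to call events down to a few hundred kb.

All coordinates are 0-based half-open (BED convention) throughout the
package; SEG output converts to 1-based inclusive at the writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# hg19 chromosome lengths (bp), chr1..chr22, chrX, chrY.
HG19_SIZES: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}

#: Default female genome table (no chrY); the expected X copy number is 2.
FEMALE_SIZES: dict[str, int] = {k: v for k, v in HG19_SIZES.items() if k != "chrY"}


@dataclass(frozen=True)
class BinScheme:
    """Ordered, disjoint, per-chromosome-contiguous genome bins.

    ``weight`` is the expected-count weight per bin (unitless, mean 1):
    proportional to bin width by construction, optionally modulated by a
    mappability-like factor estimated from flat reference cells.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.weight) == n):
            raise ValueError("BinScheme field lengths differ")
        if n == 0:
            raise ValueError("empty BinScheme")
        if np.any(self.end <= self.start):
            raise ValueError("bins must have positive width")
        if np.any(self.weight <= 0):
            raise ValueError("bin weights must be > 0")
        # contiguity within each chromosome, sorted order
        for chrom in self.chromosomes:
            sl = self.chrom_slice(chrom)
            if np.any(self.start[sl][1:] != self.end[sl][:-1]):
                raise ValueError(f"bins not contiguous on {chrom}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_start_indices(self) -> np.ndarray:
        """Global bin index of the first bin of each chromosome."""
        starts = [self.chrom_slice(c).start for c in self.chromosomes]
        return np.asarray(starts, dtype=int)

    def chrom_of_bin(self) -> np.ndarray:
        return self.chrom

    def same_chrom_as_prev(self) -> np.ndarray:
        """Boolean mask: bin i shares a chromosome with bin i-1 (False at 0)."""
        out = np.zeros(self.n_bins, dtype=bool)
        out[1:] = self.chrom[1:] == self.chrom[:-1]
        return out

    def autosome_mask(self) -> np.ndarray:
        return ~np.isin(self.chrom, ["chrX", "chrY"])

    def interval_to_bins(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Half-open global bin index range overlapping [start, end) on chrom.

        Returns (lo, hi) with hi exclusive; raises if no bin overlaps.
        """
        sl = self.chrom_slice(chrom)
        s, e = self.start[sl], self.end[sl]
        hit = np.flatnonzero((e > start) & (s < end))
        if hit.size == 0:
            raise ValueError(f"interval {chrom}:{start}-{end} overlaps no bin")
        return sl.start + int(hit[0]), sl.start + int(hit[-1]) + 1

    def mean_bin_width(self) -> float:
        return float(np.mean(self.end - self.start))

    # -- (de)serialization ----------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end,
             "weight": self.weight}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinScheme":
        w = (df["weight"].to_numpy(float) if "weight" in df.columns
             else _width_weights(df["end"].to_numpy(np.int64) - df["start"].to_numpy(np.int64)))
        return cls(
            chrom=df["chrom"].to_numpy(object),
            start=df["start"].to_numpy(np.int64),
            end=df["end"].to_numpy(np.int64),
            weight=w,
        )

    def with_weights(self, weight: np.ndarray) -> "BinScheme":
        return BinScheme(self.chrom, self.start, self.end, np.asarray(weight, float))


def _width_weights(widths: np.ndarray) -> np.ndarray:
    w = widths.astype(float)
    return w / w.mean()


def make_bin_scheme(n_bins: int, genome_table: dict[str, int] | None = None) -> BinScheme:
    """Partition a genome into ``n_bins`` bins.

    Bins are allocated to chromosomes proportionally to length (largest
    remainder, so the total equals ``n_bins`` exactly, each chromosome
    getting at least one).  Within a chromosome bins are equal-width
    (integer division) with the remainder absorbed by the last bin.
    """
    table = dict(genome_table) if genome_table is not None else dict(FEMALE_SIZES)
    if not table:
        raise ValueError("empty genome table")
    if any(length <= 0 for length in table.values()):
        raise ValueError("chromosome lengths must be > 0")
    n_chrom = len(table)
    if n_bins < n_chrom:
        raise ValueError(
            f"n_bins={n_bins} is below the number of chromosomes ({n_chrom}); "
            "every chromosome needs at least one bin"
        )

    chroms = list(table)
    lengths = np.array([table[c] for c in chroms], dtype=float)
    quota = n_bins * lengths / lengths.sum()
    alloc = np.floor(quota).astype(int)
    alloc = np.maximum(alloc, 1)
    # largest-remainder top-up / trim to hit n_bins exactly
    while alloc.sum() < n_bins:
        rem = quota - alloc
        alloc[int(np.argmax(rem))] += 1
    while alloc.sum() > n_bins:
        rem = quota - alloc
        cand = np.where(alloc > 1, rem, np.inf)
        alloc[int(np.argmin(cand))] -= 1

    chrom_col, start_col, end_col = [], [], []
    for c, k in zip(chroms, alloc):
        L = table[c]
        width = L // k
        starts = np.arange(k, dtype=np.int64) * width
        ends = np.append(starts[1:], np.int64(L))
        chrom_col.append(np.full(k, c, dtype=object))
        start_col.append(starts)
        end_col.append(ends)
    chrom_arr = np.concatenate(chrom_col)
    start_arr = np.concatenate(start_col)
    end_arr = np.concatenate(end_col)
    return BinScheme(chrom_arr, start_arr, end_arr,
                     _width_weights(end_arr - start_arr))
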