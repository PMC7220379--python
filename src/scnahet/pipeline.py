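"""End-to-end pipeline: counts -> CN -> classification -> heterogeneity.

Stages: per-cell QC and CN calling (when raw counts are given), immune
classification and cancer-cell subsetting, the sub-clonality census,
breakpoint pins, amplicon mosaicism, and clonal composition.  Every
threshold used is echoed into the JSON summary so each output is
auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import amplicons as amp
from . import cncall, io
from .genome import BinScheme
from .heterogeneity import (TumorCellSet, call_breakpoints, cluster_clones,
                            derive_pins, fraction_genome_subclonal)
from .immune import LocusRegistry, classify_pseudo_diploid, detect_vdj_deletions, is_flat_diploid

log = logging.getLogger("scnahet")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, serializable to YAML."""

    n_bins: int = 5000
    grid: tuple[float, float, float] = cncall.DEFAULT_GRID
    cbs_alpha: float = 0.01
    cbs_min_width: int = 2
    min_frac: float = 0.10
    pin_window: int = 3
    pin_low: float = 0.10
    pin_high: float = 0.90
    amp_cn_threshold: int = 5
    amp_max_span: int = 17
    dosage_cut: float = 1.5
    qc_min_reads: int = 50_000
    qc_max_zero_frac: float = 0.20
    max_aberrant_frac: float = 0.02
    clone_cut: float | None = None
    calibrate_weights: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.min_frac < 1 and 0 < self.pin_low < self.pin_high < 1):
            raise ValueError("thresholds out of range")
        if self.pin_window < 1 or self.cbs_min_width < 2:
            raise ValueError("window parameters out of range")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid"] = list(self.grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "grid" in d:
            d["grid"] = tuple(d["grid"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def call_cn_matrix(counts: np.ndarray, cell_ids: list[str], scheme: BinScheme,
                   config: PipelineConfig,
                   weights: np.ndarray | None = None,
                   ) -> tuple[TumorCellSet, list[cncall.CellProfile], list[str]]:
    """QC and CN-call every cell; returns the kept cells and profiles plus
    the IDs of excluded cells.

    Unless explicit weights are given, bin weights are calibrated from the
    sample's own flat (stromal/immune) nuclei when enough are present —
    the internal diploid reference that absorbs mappability variation.
    """
    if weights is None and config.calibrate_weights:
        weights = cncall.calibrate_bin_weights(counts, scheme)
        if weights is not None:
            log.info("bin weights calibrated from flat reference cells")
    profiles, kept_rows, kept_ids, dropped = [], [], [], []
    for i, cid in enumerate(cell_ids):
        ok, reason = cncall.qc_cell(counts[i], config.qc_min_reads,
                                    config.qc_max_zero_frac)
        if not ok:
            dropped.append(cid)
            log.info("QC drop %s (%s)", cid, reason)
            continue
        prof = cncall.call_cell(counts[i], scheme, cell_id=cid,
                                alpha=config.cbs_alpha,
                                min_width=config.cbs_min_width,
                                grid=config.grid, weights=weights,
                                seed=config.seed)
        profiles.append(prof)
        kept_rows.append(prof.cn)
        kept_ids.append(cid)
    if not kept_rows:
        raise ValueError("no cells passed QC")
    cells = TumorCellSet(np.vstack(kept_rows), kept_ids, scheme)
    return cells, profiles, dropped


def classify_cells(cells: TumorCellSet, registry: LocusRegistry | None = None,
                   config: PipelineConfig | None = None) -> pd.Series:
    """Assign each cell exactly one class.

    Pass 1: cells flat outside the immune loci become T / B / X-loss-T /
    flat-stromal from their receptor-locus deletions.  Pass 2: the
    remaining aberrant cells define breakpoint pins; aberrant cells
    sharing too few clonal pins are pseudo-diploid, the rest cancer.
    """
    config = config or PipelineConfig()
    registry = registry or LocusRegistry()
    scheme = cells.scheme
    locus_mask = registry.all_bins(scheme)
    classes = np.empty(cells.n_cells, dtype=object)

    aberrant_idx = []
    for i in range(cells.n_cells):
        cn = cells.matrix[i]
        if is_flat_diploid(cn, scheme, config.max_aberrant_frac,
                           exclude=locus_mask):
            call = detect_vdj_deletions(cn, scheme, registry,
                                        cell_id=cells.cell_ids[i])
            classes[i] = call.cell_class
        else:
            aberrant_idx.append(i)

    if aberrant_idx:
        bps = [call_breakpoints(cells.matrix[i], scheme) for i in aberrant_idx]
        clonal_pins = None
        if len(aberrant_idx) >= 2:
            pins = derive_pins(bps, window=config.pin_window,
                               low=config.pin_low, high=config.pin_high)
            clonal_pins = pins.bins("clonal")
        for i in aberrant_idx:
            verdict = classify_pseudo_diploid(
                cells.matrix[i], scheme, clonal_pins, registry,
                window=config.pin_window,
                min_aberrant_frac=config.max_aberrant_frac)
            if verdict == "flat":
                classes[i] = "flat-stromal"
            elif verdict == "immune":
                classes[i] = detect_vdj_deletions(
                    cells.matrix[i], scheme, registry,
                    cell_id=cells.cell_ids[i]).cell_class
            else:
                classes[i] = verdict
    return pd.Series(classes, index=cells.cell_ids, name="cell_class")


def run_pipeline(counts: np.ndarray | None, scheme: BinScheme,
                 config: PipelineConfig, cell_ids: list[str] | None = None,
                 cn_cells: TumorCellSet | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run every stage and return (and optionally write) the summary.

    Give either raw ``counts`` (cells x bins, with ``cell_ids``) or an
    already-called ``cn_cells`` matrix.  Determinism: identical config and
    inputs give an identical summary.
    """
    config.validate()
    registry = LocusRegistry()
    summary: dict = {"thresholds": {
        "min_frac": config.min_frac, "pin_window": config.pin_window,
        "pin_low": config.pin_low, "pin_high": config.pin_high,
        "amp_cn_threshold": config.amp_cn_threshold,
        "amp_max_span": config.amp_max_span,
        "cbs_alpha": config.cbs_alpha, "cbs_min_width": config.cbs_min_width,
        "grid": list(config.grid), "seed": config.seed,
    }}
    profiles = None
    dropped: list[str] = []
    if cn_cells is None:
        if counts is None:
            raise ValueError("need counts or a CN matrix")
        if cell_ids is None:
            cell_ids = [f"cell_{i:04d}" for i in range(counts.shape[0])]
        cn_cells, profiles, dropped = call_cn_matrix(counts, cell_ids,
                                                     scheme, config)
    summary["n_cells_input"] = len(dropped) + cn_cells.n_cells
    summary["n_cells_qc_dropped"] = len(dropped)

    classes = classify_cells(cn_cells, registry, config)
    census = classes.value_counts().to_dict()
    summary["immune_census"] = {str(k): int(v) for k, v in census.items()}
    log.info("cell classes: %s", census)

    cancer_mask = (classes == "cancer").to_numpy()
    summary["n_cancer_cells"] = int(cancer_mask.sum())
    if cancer_mask.sum() == 0:
        summary["heterogeneity"] = {"status": "skipped: no cancer cells"}
        if outdir is not None:
            _write_outputs(outdir, config, scheme, cn_cells, classes,
                           profiles, summary)
        return summary

    cancer = cn_cells.subset(cancer_mask)
    pct = fraction_genome_subclonal(cancer.matrix, config.min_frac)
    bps = [call_breakpoints(cancer.matrix[i], scheme)
           for i in range(cancer.n_cells)]
    het: dict = {"pct_genome_subclonal": pct}
    if cancer.n_cells >= 2:
        pins = derive_pins(bps, window=config.pin_window,
                           low=config.pin_low, high=config.pin_high)
        het["n_pins_clonal"] = pins.count("clonal")
        het["n_pins_subclonal"] = pins.count("sub-clonal")
        het["n_pins_rare"] = pins.count("rare")
        comp = cluster_clones(cancer.matrix, cut=config.clone_cut)
        het["composition_class"] = comp.composition_class
        het["clone_frequencies"] = {str(k): round(v, 4)
                                    for k, v in comp.frequencies.items()}
    summary["heterogeneity"] = het

    locus_mask = registry.all_bins(scheme)
    ampmat = amp.amplicon_presence_matrix(cancer.matrix, scheme,
                                          config.amp_cn_threshold,
                                          config.amp_max_span)
    flags, tumor_mosaic = amp.detect_mosaicism(ampmat.presence,
                                               config.min_frac)
    homdels = sorted({iv for i in range(cancer.n_cells)
                      for iv in amp.detect_homozygous_deletions(
                          cancer.matrix[i], scheme,
                          exclude_mask=locus_mask)})
    summary["amplicons"] = {
        "n_amplicons": len(ampmat.intervals),
        "n_mosaic_amplicons": int(np.sum(flags)),
        "tumor_mosaic": tumor_mosaic,
        "intervals": [list(iv) for iv in ampmat.intervals],
        "n_homozygous_deletion_loci": len(homdels),
    }

    if outdir is not None:
        _write_outputs(outdir, config, scheme, cn_cells, classes, profiles,
                       summary)
    return summary


def _write_outputs(outdir: str | Path, config: PipelineConfig,
                   scheme: BinScheme, cells: TumorCellSet, classes: pd.Series,
                   profiles, summary: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    io.write_bin_scheme(scheme, outdir / "bins.bed")
    io.write_cn_matrix(cells, outdir / "cn_matrix.tsv")
    classes.to_frame().to_csv(outdir / "cell_classes.tsv", sep="\t")
    if profiles is not None:
        seg_path = outdir / "segments.seg"
        for k, prof in enumerate(profiles):
            io.write_seg(prof.segments, scheme, prof.cell_id, prof.cn,
                         seg_path, mode="w" if k == 0 else "a")
    io.write_json(summary, outdir / "summary.json")
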