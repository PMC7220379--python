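"""Bulk arm-dosage scoring and survival stratification.

Gains of 1q and 8q are cytogenetically coupled to 16q loss in breast
cancer.  For each bulk sample with segmented absolute copy number, the
module computes segment-length-weighted mean CN per arm, normalizes the
larger of the 1q/8q means by the 16q mean (so ploidy cancels and diploid
and polyploid tumors are scored on one scale), classifies samples as
high (score > 1.5) vs low, filters to cases with 16q loss plus a 1q or
8q gain, and compares time to distant relapse between classes with a
Kaplan-Meier / log-rank analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: hg19 q-arm intervals (centromere to qter) for the three arms of interest.
DEFAULT_ARMS: dict[str, tuple[str, int, int]] = {
    "1q": ("chr1", 125_000_000, 249_250_621),
    "8q": ("chr8", 45_600_000, 146_364_022),
    "16q": ("chr16", 36_600_000, 90_354_753),
}

DOSAGE_CUT = 1.5


@dataclass
class ArmDosageRecord:
    sample_id: str
    mean_1q: float
    mean_8q: float
    mean_16q: float
    score: float
    dosage_class: str          # high | low
    eligible: bool
    baseline_ploidy: float


def arm_mean_cn(segments: pd.DataFrame, arm: tuple[str, int, int]) -> float:
    """Segment-length-weighted mean absolute CN over an arm.

    ``segments`` has columns chrom, start, end (0-based half-open, bp) and
    cn (absolute copies).  Segments are clipped to the arm interval.
    Returns NaN when nothing overlaps.
    """
    chrom, a_start, a_end = arm
    sub = segments[segments["chrom"] == chrom]
    if sub.empty:
        return float("nan")
    start = np.maximum(sub["start"].to_numpy(np.int64), a_start)
    end = np.minimum(sub["end"].to_numpy(np.int64), a_end)
    lengths = np.maximum(end - start, 0)
    if lengths.sum() == 0:
        return float("nan")
    cn = sub["cn"].to_numpy(float)
    return float(np.sum(lengths * cn) / lengths.sum())


def dosage_score(mean_1q: float, mean_8q: float, mean_16q: float) -> float:
    """max(mean 1q, mean 8q) / mean 16q — the 16q-normalized gain level."""
    if not mean_16q > 0:
        raise ValueError("16q mean must be > 0")
    return max(mean_1q, mean_8q) / mean_16q


def classify_dosage(score: float, cut: float = DOSAGE_CUT) -> str:
    """high iff score strictly exceeds the cut (1.5); boundary is low."""
    return "high" if score > cut else "low"


def modal_ploidy(segments: pd.DataFrame) -> float:
    """Length-weighted modal integer CN over the genome — the baseline
    against which arm gains/losses are judged."""
    lengths = (segments["end"] - segments["start"]).to_numpy(np.int64)
    cn = np.round(segments["cn"].to_numpy(float)).astype(int)
    if lengths.sum() <= 0:
        raise ValueError("segments carry no genomic length")
    levels = np.unique(cn)
    weights = np.array([lengths[cn == lv].sum() for lv in levels])
    return float(levels[int(np.argmax(weights))])


def eligibility_filter(mean_1q: float, mean_8q: float, mean_16q: float,
                       baseline: float, margin: float = 0.10) -> bool:
    """Eligible iff 16q is lost and 1q or 8q is gained, relative to the
    sample's modal-ploidy baseline with a 10% relative margin."""
    if not np.isfinite(baseline) or baseline <= 0:
        return False
    loss_16q = mean_16q < baseline * (1.0 - margin)
    gain = (mean_1q > baseline * (1.0 + margin)) or \
           (mean_8q > baseline * (1.0 + margin))
    return bool(loss_16q and gain)


def score_sample(sample_id: str, segments: pd.DataFrame,
                 arms: dict[str, tuple[str, int, int]] | None = None,
                 cut: float = DOSAGE_CUT, margin: float = 0.10) -> ArmDosageRecord:
    arms = arms or DEFAULT_ARMS
    m1q = arm_mean_cn(segments, arms["1q"])
    m8q = arm_mean_cn(segments, arms["8q"])
    m16q = arm_mean_cn(segments, arms["16q"])
    base = modal_ploidy(segments)
    score = dosage_score(m1q, m8q, m16q)
    return ArmDosageRecord(
        sample_id=sample_id, mean_1q=m1q, mean_8q=m8q, mean_16q=m16q,
        score=score, dosage_class=classify_dosage(score, cut),
        eligible=eligibility_filter(m1q, m8q, m16q, base, margin),
        baseline_ploidy=base)


def km_stratify(records: pd.DataFrame, time_col: str = "time",
                event_col: str = "event",
                class_col: str = "dosage_class") -> dict:
    """Kaplan-Meier curves per dosage class plus a two-sided log-rank test.

    ``records`` holds one row per sample with time to distant relapse,
    the event flag, and the high/low class.  Returns survival tables per
    class, the log-rank p, and a flag when any class has zero events.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    if np.any(records[time_col].to_numpy(float) < 0):
        raise ValueError("times must be >= 0")
    curves = {}
    zero_event = False
    for cls, grp in records.groupby(class_col):
        kmf = KaplanMeierFitter()
        kmf.fit(grp[time_col], grp[event_col], label=str(cls))
        sf = kmf.survival_function_
        curves[str(cls)] = pd.DataFrame(
            {"time": sf.index.to_numpy(float),
             "survival": sf.iloc[:, 0].to_numpy(float)})
        if grp[event_col].sum() == 0:
            zero_event = True

    classes = records[class_col].unique()
    p = float("nan")
    if len(classes) == 2:
        a = records[records[class_col] == classes[0]]
        b = records[records[class_col] == classes[1]]
        res = logrank_test(a[time_col], b[time_col],
                           event_observed_A=a[event_col],
                           event_observed_B=b[event_col])
        p = float(res.p_value)
    return {"curves": curves, "logrank_p": p, "zero_event_class": zero_event}
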