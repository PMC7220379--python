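# Methods

This note records the models, parameter choices and numerical decisions
behind `scnahet`, and what the synthetic data can and cannot establish
about behavior on real sequencing data.

## Bin schemes and coordinates

The genome is partitioned into `n_bins` fixed bins (default 5000, ~600 kb
for a human genome), allocated to chromosomes proportionally to length by
largest remainder (total exactly `n_bins`, every chromosome ≥1 bin) and
equal-width within a chromosome, the division remainder absorbed by the
last bin.  All in-memory and BED/TSV coordinates are 0-based half-open;
SEG files are written and read in the conventional 1-based inclusive
dialect with conversion at the I/O boundary.  The default genome table is
the hg19 female karyotype (chr1–22 + X, expected X copy number 2);
expected sex-chromosome baselines are configurable.

Each bin carries an expected-count weight (mean 1).  By default it is
width-proportional; when a sample contains ≥3 flat (copy-number-neutral)
nuclei, the pipeline pools their reads and re-estimates the weights
(`calibrate_bin_weights`), absorbing mappability/GC-like bin biases the
way binned-count protocols calibrate against normal reference samples.
Two deliberate details: (i) the V(D)J receptor-locus windows are excluded
from calibration — lymphocytes in the reference pool are somatically
deleted there, which would bias those bins 15–30% low — and keep
width-proportional weights; (ii) "flat-like" reference cells are screened
cheaply by requiring every chromosome's mean normalized ratio within 0.10
of 1, which rejects any cell with arm-scale CNAs while keeping cells
whose only lesions are focal (V(D)J deletions).

## Normalization and segmentation

Ratios are `(count/weight)` scaled to mean exactly 1.  Segmentation is a
bundled circular-binary-segmentation engine: within a candidate segment
the best contiguous window is the one maximizing the pooled two-sample
t-statistic against the segment's complement (window/complement symmetry
makes linear windows equivalent to circular arcs), and the segment is
split at the window edges if the statistic is significant; recursion
proceeds until no significant split remains.  Minimum segment width is 2
bins (default `alpha` 0.01).

Significance is decided by a hybrid rule, in order:

1. **Exact piecewise-constant shortcut.**  If the segment is exactly
   piecewise constant with every run ≥ `min_width`, run boundaries are
   returned directly.  This makes the noise-free behavior independent of
   `alpha`; a pure permutation test cannot, since its p-values are
   floored at 1/(n_perm+1).  Continuous noise makes ties measure-zero, so
   the shortcut never fires on noisy data.
2. **Fast paths.**  A max-t above √(2·log n_pairs) + 3 (far beyond the
   expected null maximum for the segment's length) splits without
   permutations; a max-t below 2 never splits.
3. **Permutation band.**  Otherwise up to 200 within-segment shuffles
   estimate the null, early-stopped as soon as the exceedance count
   proves p ≥ alpha.  In practice almost every decision at realistic
   depth takes a fast path, which keeps per-cell segmentation at tens of
   milliseconds for ~1000 bins.

## Integer quantization

The ploidy multiplier minimizes the length-weighted squared distance of
scaled segment means to integers over a grid (default 1.5–6.0, step 0.05
— wide enough for hypodiploid through near-hexaploid genomes; the grid is
exposed because no canonical search range exists).  Three guards matter
in practice:

- **Short segments are excluded from the fit** (< 5 bins; they still
  receive rounded CN).  Changepoint jitter produces short segments that
  straddle two true states and sit near half-integer copy number; those
  are maximally penalized at the true multiplier and fit perfectly at its
  double, so including them systematically favors the doubled-ploidy
  harmonic.
- **Exact grid ties** (all-even copy-number states fit m and 2m equally)
  break toward a flow-sort ploidy hint when provided, else toward the
  smallest tied multiplier.  With noise, the larger harmonic amplifies
  residuals and loses naturally.
- **Flat genomes** (segment-mean spread < 0.12, well below the 1/6
  minimum spacing of distinct states at the grid ceiling) make the fit
  ill-posed; the cell is declared diploid and flagged, with segment CN
  assigned by rounding under the diploid assumption so that focal events
  in otherwise-flat cells (V(D)J deletions, lone amplicons) survive.

After quantization, isolated near-zero-ratio bins (< 0.1) inside non-zero
segments are set to CN 0 when mean depth exceeds 100 reads/bin — at that
depth a zero count is conclusive, and this preserves homozygous deletions
narrower than the minimum segment width (1-bin V(D)J deletions).

Down-sampling to a common depth (used before breakpoint comparisons) is a
multivariate hypergeometric draw: exactly the target total, without
replacement, seeded.

## Heterogeneity statistics

Census: a bin is sub-clonal iff ≥2 copy-number states are each carried by
≥10% of cancer nuclei (boundary inclusive); % genome sub-clonal is 100 ×
sub-clonal bins / total bins, computed on cancer cells only after immune
and pseudo-diploid cells are removed.  Pins: per-cell breakpoints (left
bin index of each state change; chromosome boundaries never count) are
merged greedily — the 3-bin window with the highest cell support becomes
a pin anchored at its modal bin (leftmost on ties), its breakpoints are
consumed, and the search repeats.  Labels are clonal strictly above 0.90,
rare at or below 0.10, and sub-clonal between; a supporting fraction of
exactly 0.90 is sub-clonal (the boundary is undefined by the >90% / <90%
wording, and this choice keeps the partition total).

Clone clustering is hierarchical (L1 distance over integer CN, average
linkage) cut at cophenetic distance max(5, 1% of bins) — within-clone
distances are noise-driven (a few bins), between-clone distances at least
the number of differing bins.  Clusters below max(2, 5% of cells) are
unassigned.  Composition classes: homogeneous when the top clone holds
≥95% of assigned cells (a 5% tolerance for unassigned/noise cells),
dominant above 50%, else no-dominant.  Association wrappers use the exact
small-sample Mann–Whitney (Wilcoxon rank-sum) test for two-level factors
and Spearman rank correlation for continuous covariates.

## Immune cells and clonality

Default hg19 locus windows: TCRa chr14:22.09–23.03 Mb, TCRb
chr7:142.00–142.51 Mb, IGH chr14:106.03–107.29 Mb, IGL chr22:22.38–23.27
Mb, padded by 7 bins on each side when resolved against a scheme (at
~600 kb bins a sub-megabase deletion's evidence smears over neighboring
bins; observed breakpoint spreads cover ~14 bins).  Padded windows that
collide on a coarse scheme are split at the midpoint so every bin belongs
to at most one locus.

Classification partitions every cell: flat outside the immune loci →
T / B / X-loss-T / flat-stromal from CN-0 runs of 1–5 bins (homozygous
only; CN 1 dips are not evidence; B requires an Ig deletion and no TCR
deletion); aberrant cells are pseudo-diploid when they carry no immune
deletion and match <20% of the tumor's clonal pins, else cancer;
aberrant cells without any tumor signature are "aberrant-unassigned".
X-loss requires the X median one copy below baseline with ≥90% of X bins
at that state.

The breakpoint distance is |Δleft| + |Δright| in bins (an L1 metric).
The clonality test samples `g`-sets from a reference pool without
replacement (default 10⁶ draws), statistic = all sampled cells share
identical breakpoint bins after common-depth re-segmentation; p =
(1+hits)/(1+n_perm), reported as "<1/n_perm" at zero hits.  Where a
closed form exists (k identical cells among N otherwise unique) it equals
C(k,g)/C(N,g), which the tests verify to Monte-Carlo precision.

## Amplicons, multi-region, arm dosage

Amplification is CN strictly greater than 5, in maximal runs of at most
17 bins (~10 Mb — chosen to separate focal amplicons from arm gains, and
configurable since no canonical focality limit exists); longer runs are
broad gains.  Per-cell intervals are union-merged across cells; presence
is evaluated per cell as max CN within the merged interval against the
same threshold.  Mosaicism requires presence in ≥10% and absence in ≥10%
of cancer cells.  Dosage strata default to a single break at 30 copies
with the same 10% two-sided rule.  Mutual exclusivity is scipy's Fisher
exact test (one-sided, under-co-occurrence) with the conditional-MLE odds
ratio and exact CI; zero margins flag the result with p = 1.  Homozygous
deletions are CN-0 runs ≤5 bins outside the immune loci.

Bulk differentials are maximal runs of unequal integer CN ≥5 bins; a
differential is recovered in cells when ≥10% of cells match the other
biopsy's state over ≥50% of the interval (the overlap fraction absorbs
segmentation boundary jitter).

Arm dosage uses segment-length-weighted means over configurable arm
intervals (hg19 1q/8q/16q defaults), score = max(1q, 8q)/16q, high
strictly above 1.5.  Eligibility (16q lost and 1q or 8q gained) is judged
against the sample's length-weighted modal integer CN with a 10% relative
margin — an explicit stand-in for cellularity-dependent calling
thresholds, exposed as a parameter.  Survival stratification is
lifelines' Kaplan–Meier and two-sided log-rank test.

## The synthetic-data generator

`simulate_sample` emulates the target protocol: default 116 nuclei and
2×10⁶ reads per nucleus on 5000 bins (a 500-bin/10⁵-read preset exists
for fast experiments).  Clones form a parent tree; each clone's CN vector
is its baseline ploidy (2 or 4) plus inherited and private events.  Reads
are placed multinomially with probability ∝ true CN × bin weight, where
weights carry lognormal jitter (σ = 0.1) mimicking mappability/GC
variation; no explicit GC model, read-level errors, or doublets.
T-cells are flat diploid with a TCRa deletion (TCRb with probability
0.5), width 1–3 bins uniform, breakpoints uniform over the padded locus
window (capped at a 14-bin span); B-cells carry IGH and IGL deletions; a
configurable fraction of T-cells loses one X copy.  Pseudo-diploids carry
1–4 private arm-scale CNAs (3–8% of genome bins each) on distinct
chromosomes, matching the prototypical arm-level gains/losses such nuclei
display; the stromal fraction is whatever cell count remains.  Bulk
region pairs are mixture-weighted means of clone CN rounded half-to-even.
Identical (config, seed) gives bit-identical output; per-cell counts sum
exactly to `reads_per_cell`.

What passing tests on this generator do **not** show: amplification
dropout and coverage dispersion of real whole-genome-amplified nuclei
(real T/B-cell detection sensitivities are substantially below the
near-100% achieved here), GC waves, segmentation behavior under
heavy-tailed noise, and doublet contamination.  The generator validates
the *logic* of every stage against known truth, not instrument noise.

## Problem sizes used in tests and the acceptance script

Experiments are scaled so the whole suite runs quickly while leaving the
per-read and per-bin noise regime realistic: end-to-end samples use
100–116 cells at 800 bins and 5×10⁵ reads/cell; multiplier-recovery runs
200 cells at 1000 bins and the full 2×10⁶ reads; purified-population
sensitivity uses 96 nuclei at 2000 bins (where locus windows span
multiple bins); the clonality oracle uses 10⁵ draws per configuration
and the pipeline default remains 10⁶.  These sizes are the package's
validation choices, stated here so they can be scaled up freely.

## Known limitations

- CBS fast-path thresholds are calibrated for the depths simulated here;
  at very low depth (<100 reads/bin) the permutation band dominates and
  runtime grows.
- The multiplier grid cannot represent ploidies above 6; genuinely
  higher-ploidy nuclei would be folded onto a harmonic.
- Pseudo-diploid vs cancer discrimination depends on the tumor having a
  clonal pin signature; tumors with few clonal breakpoints give the
  <20%-shared rule little to work with, and occasional breakpoint
  collisions misassign single cells.
- The eligibility margin (10%) and the amplicon focality limit are
  pragmatic defaults, not derived quantities; both are configuration
  fields.
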