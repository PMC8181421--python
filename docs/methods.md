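# Methods

This note documents the models, parameter choices and numerical conventions
behind `atacmem`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinate and data conventions

All coordinates are 0-based half-open `[start, end)` (BED standard). Every
window operation is summit-anchored and half-open: counting windows are
`[summit − 200, summit + 200)`, motif windows `[summit − 100, summit + 100)`,
tag-density windows 2,000 bp in 10 bp bins. Book-ended intervals (gap 0)
merge, matching common sort-and-merge tool behavior. Peaks are unstranded;
strand is carried on intervals and genes but ignored by set operations.

Nearest-gene assignment minimizes |summit − TSS| on the same chromosome,
with ties broken by smaller TSS and then lexicographic gene id, and reports
the signed distance `TSS − summit`. Summit-to-TSS (rather than edge-to-TSS)
distance was chosen because the summit anchors every other window operation;
the tie rule is a documented package convention, not an inference about any
other tool's behavior.

## Peak calling

The caller is a transparent local-Poisson scan, standing in for a MACS-style
caller so the pipeline has no external binary dependency:

* window 150 bp (default), slid at every bp via cumulative sums;
* null rate = max(genome-wide mean, local mean over 10 kb centred on the
  window); upper-tail Poisson p per window; significance at p < 1e−5;
* significant windows are unioned and merged into regions;
* the summit is the bp maximizing a 21 bp moving sum of combined-strand
  cuts, with plateau ties resolved by raw count then leftmost position —
  the smoothing makes the summit robust to per-bp Poisson noise;
* the score is −log10 p of the window centred on the summit.

All parameters are configurable. Lambda smoothing tiers, fragment-size
modeling and paired-end reconstruction are deliberately out of scope. On the
standard synthetic design (below) the caller reaches sensitivity ≥ 0.98 with
median summit error ~11 bp at 100 cuts/peak over a 0.005 cuts/bp background.

Replicate concordance intersects the top 35,000 peaks (by score) of the two
replicates, keeping replicate 1's coordinates. Condition sets are merged
into the master set; when regions merge, the summit of the highest-scoring
contributor wins. Re-calling peaks on pooled raw data would be the
alternative; it requires the original fragments, so the highest-score-
contributor rule is used and documented here.

## Normalization

`size_factors_topN` computes, per sample, the median of that sample's own
top-N window counts (N = 30,000 by default; all features when fewer) and
references it to the geometric mean over samples, which makes the factors
symmetric and scale-free. "Top" means top by the sample's own raw counts,
ties at the cutoff broken by coordinate. Dividing by the factors equalizes
top-N medians to machine precision, which the tests assert at 1e−9. The
median-of-ratios scheme used by standard RNA-seq count testing is exposed as
an alternative mode (`size_factors_median_of_ratios`) and is the default for
the expression matrix, where a top-N scheme has no special motivation.

## The negative-binomial Wald test

Counts are modeled NB with `Var = μ + αμ²`.

* **Dispersion.** Within each group, the moment estimator
  `α̂ = max(0, (s² − μ̄)/μ̄²)` on size-factor-normalized counts, pooled
  across the two groups weighted by degrees of freedom, then shrunk toward
  the across-feature mean with weight 0.5 and clamped to `[1e−8, 10]`.
  Estimates falling below the across-feature trend are raised to the trend:
  with two or three replicates per group a below-trend moment estimate is
  far more often noise than signal, and keeping it understates that
  feature's standard error. This asymmetric treatment is what standard
  count-testing frameworks converge on, and it is what makes the test
  calibrated at small n (measured type-I fraction at p < 0.05 is 0.043–0.051
  across seeds for a 10,000-feature null at α = 0.1, n = 3+3, depth 100,
  with ~1 Benjamini–Hochberg discovery).
* **Means.** Group means with size-factor offsets are fitted by maximum
  likelihood at fixed α via the fixed-point iteration
  `m ← Σ y/(1+αsm) / Σ s/(1+αsm)` (the rearranged score equation), started
  at the size-factor-corrected sample mean.
* **Statistic.** `log2FC = log2(m_B/m_A)`; when either MLE mean is zero,
  0.5 is added to both means so the fold change stays finite. The SE comes
  from the Fisher information `I_g = Σ_j μ_j/(1+αμ_j)` for each group's
  log-mean; p is two-sided normal. Degenerate SEs (identical constant
  counts; both groups zero) yield p = 1. The test is exactly symmetric
  under group swap.

The full machinery of trended-GLM dispersion fits, Cox–Reid adjustment,
LFC shrinkage, independent filtering and outlier replacement is *not*
reproduced; the design goal is a transparent, calibration-validated test.

One boundary fact worth knowing: under the detection rule
"padj < 0.05 **and** observed |log2FC| ≥ log2 3", an effect planted at
exactly 3-fold is detected only ~50% of the time regardless of power,
because the observed fold change falls on either side of its true value
symmetrically. Detection rates quoted in the tests therefore use planted
effects away from the threshold (≥ 0.98 at 8-fold, ≥ 0.6 at 3.5-fold,
both measured).

## DHS classification and summaries

A peak is "up" for a contrast when FC > 3 (strict inequality, configurable
to ≥), padj < 0.05, and the normalized count exceeds 20 in **both**
replicates of the higher-mean group — a peak must demonstrably exist where
it is claimed gained; "down" is the mirror image. Up and down are mutually
exclusive by construction and the code asserts it. Raising the fold
threshold can only shrink category sets (tested). Per-contrast fold
thresholds are configurable (e.g. 2-fold for effector- vs central-memory
style comparisons).

`stability_summary` counts reference peaks whose later-timepoint fold
change still meets each threshold; `transient_fraction` counts early-
suppressed peaks whose later signal no longer meets the suppression
criterion. Percentages print as integers except when the first decimal is
exactly 5 after rounding, which keeps one decimal — so 97.46% prints as
97.5 while 83.33% prints as 83, matching how such mixed-precision pairs are
conventionally reported.

## Peak-to-gene integration

Each peak maps to one nearest gene; a gene may collect several peaks. A
gene's exclusive class is: mDHS+iDHS if it has both; otherwise mDHS-only,
iDHS-only, or dDHS-only (dDHS-only requires no mDHS/iDHS peak); genes with
only nDHS peaks or no categorized peak fall in "none". Gene-set expression
summaries report the arithmetic mean log2FC with a 95% percentile bootstrap
CI (1,000 resamples, seeded) — the CI construction is this package's
choice and is labeled as such. Primed-inducible genes are those ≥ 3-fold up
in the stimulated-vs-memory contrast that were already ≥ 3-fold up in
memory-vs-naive; gene-level differential criteria are 3-fold and
padj < 0.05 with no minimum-count rule (an optional one can be configured).

## Motifs and footprints

Motifs are IUPAC consensus strings (panel: ETS AGGAAGTG, RUNX TGTGGTTT,
AP-1 TGASTCA, TCF/LEF CTTTGWW, T-box AGGTGTGA, NFAT TTTTCCA, EGR
GCGBGGGCG; any TSV of name/consensus works), matched exactly on both
strands with an optional mismatch budget. Consensus matching (rather than
PWM log-odds scoring) is sufficient for planted-truth testing and keeps
the scan an exact, oracle-checkable operation; enrichment numbers are
therefore not comparable to de novo discovery tools.

Footprint scoring is strand-aware: a bound factor shields its motif so the
forward-strand signature appears against the upstream shoulder and the
reverse-strand signature against the downstream shoulder (35 bp each).
Per strand, `p = P[Binom(n = k_fp + k_sh, q = L/(L + 35)) ≤ k_fp]`; the
combined score is the sum of the two −log10 p values, passing at ≥ 10.
This is a deliberate simplification of published footprinting statistics
(which add FDR calibration and multi-scale windows); it is validated by
planted-footprint recovery, not by tool equivalence: on the standard
design's pooled tracks, protected instances pass at ~100% while uniform
null instances pass at ≤ 1% (measured 0%).

Average cut profiles align instances on the motif center, flip
reverse-strand instances (strands swapped, positions mirrored), and keep
strands separate. Tag-density matrices bin combined-strand counts (2,000 bp
windows, 10 bp bins, size-factor scaled); a profile row summed over bins
equals the summit-window count at the same halfwidth, an internal
consistency the tests assert.

## The synthetic-data generator

The generator emulates the multi-condition memory T-cell experiment:
conditions N, M7, M28, M56, M28Ag, M56Ag with two replicates each, and
per-peak accessibility multipliers by category (effect size 8 by default):

* mDHS: ×8 in all memory conditions, with late-timepoint sub-structure —
  83% stay ×8 at M56, 14.5% decay to ×2.5, 2.5% to ×1.5;
* nDHS: ×8 in naive; 45% are transient (suppressed at M7, restored to
  ×0.8 of naive from M28 on), the rest stay suppressed;
* iDHS ×8 / dDHS ×(1/8) in the antigen-stimulated conditions;
* constitutive: uniform jitter in [0.9, 1.1].

These sub-fractions mirror the dynamics regime the pipeline is designed to
summarize and were fixed up front as generator defaults. The standard scale
is 2 chromosomes × 5 Mb, 2,000 peaks (including 100 gene pairs that carry
both an mDHS and an iDHS around a shared TSS), depth 100, NB dispersion
0.1, per-sample size factors drawn uniformly in [0.6, 1.6] — it runs in
seconds.

Counts are NB draws around depth × multiplier × size factor. Cut tracks
place Poisson totals per peak with per-bp weights that are either uniform
or (default) a truncated Gaussian of σ = width/4 centred on the summit; the
peaked profile is what makes summit recovery to ≤ 25 bp possible at this
depth, while the uniform profile is retained for null calibration tests
where a flat rate is the hypothesis under test. Protected planted motifs
multiply the per-bp rate by 0.1 inside the motif and 1.5 in the 10 bp
flanks — the minimal shape producing the canonical footprint signature.
Footprinting operates on tracks pooled across samples, as footprinting
tools are conventionally run on merged data. Expression counts follow the
linked peak's category (coupling log2FC 2 by default, a +1 extra boost for
dual mDHS+iDHS genes under stimulation, 10% of genes decoupled).

Everything is deterministic given the config seed, with independent
substreams per product (truth, counts, per-sample tracks, genome,
expression) so regenerating one output never perturbs another.

**What the synthetic tests do not show.** The generator has no sequence
composition bias, fragment-length structure, mitochondrial contamination,
duplicate reads, copy-number variation, or peak-width heterogeneity, and
its noise is exactly the NB the test assumes. Passing recovery tests
demonstrates the pipeline's operations are implemented correctly and
calibrated under their stated model — not that the model captures every
failure mode of real ATAC-seq libraries.

## Problem sizes

The test suite and the acceptance script run the standard 2,000-peak design
for count-based analyses, pooled 10 Mb cut tracks for footprinting, and a
10,000-feature null for test calibration; oracle-equivalence checks use
randomized instances of a few hundred items where brute force is exact.
These sizes give stable Monte-Carlo estimates (binomial SEs well below the
asserted margins) while keeping a full run in minutes on one core.
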