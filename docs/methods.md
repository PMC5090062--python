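# Methods

This note documents the models, estimators and design choices behind
`mirhsr`, and what the synthetic benchmark does and does not establish.

## Study design emulated by the generator

Three fly strains (defaults named `w1118`, `hsp70`, `yw`) are sampled at a
25 °C control point and at 1, 6 and 24 h of recovery after severe heat
shock, with 2 replicate libraries per condition.  Each of `n_mirnas`
hairpins yields a 5p and a 3p mature miRNA; the dominant arm is 1–5 log₂
above the minor arm.  Mature abundances are compositional: per sample the
mean vector is renormalized so the expected column total equals
`depth × size_factor`, with per-sample size factors drawn
log-normal(0, 0.1) so library-size normalization does real work.  Counts
are gamma-Poisson (negative binomial) with a single dispersion φ
(default 0.1; depth default 2×10⁶ reads — both are benchmark choices, set
once to typical small-RNA-library values).

Effect structure, all in log₂ relative to a miRNA's baseline:

- **class #1 (levelling, default 10 % of matures)** — per-strain control
  offsets drawn from {−e, 0, +e} (e = `level_effect_log2`, default 2), not
  all equal; at 1 h and 6 h all strains sit at the common level; at 24 h
  the offset returns at 70 % of its control value (`recovery_fraction`),
  mimicking partial recovery.
- **class #2 (HS-divergent, default 10 %)** — equal control means;
  per-strain divergences from the same {−e, 0, +e} scheme applied at 1 h
  and decaying (×1, ×0.6, ×0.2 over the recovery points).
- **polycistronic clusters** — consecutive same-strand hairpins share a
  primary-transcript trajectory (per-timepoint N(0, 1.2)) plus per-mature
  N(0, 0.2) deviations.
- every mature additionally receives a mild strain-independent response
  (N(0, 0.3) per post-HS timepoint), which cancels in strain contrasts.

Alignments realize each count as a 21–23 nt read inside the mature
interval (±1 nt jitter), mature-sense sequence carried in the BED name
column.  Editing sites substitute A→G or T→C per read with the stated
frequency (the generator patches the reference so the site carries the
required base); background errors are per-base Bernoulli
(`seq_error_rate`, default 10⁻³).  Target-prediction algorithms keep each
true edge with probability `sensitivity` and add non-edges at `fpr`,
independently per algorithm.  The toy ontology is a random DAG (default 60
terms, depth 4) with true-path-propagated annotations.

What the generator does **not** emulate: hairpin folding or cut-site
realism, isomiR 5′ heterogeneity, sequencing-quality structure, adapter
artefacts, correlated dispersion trends, or a realistic GO topology.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated model, not performance on real
libraries.

## Counting

Internal coordinates are 0-based half-open; GFF3 is converted once at the
boundary.  A read is assigned to the single mature feature with the
largest overlap among those on the same strand, with read length in 18–26
nt and overlap ≥ 50 % of the read length; ties break by leftmost feature
start, then lexicographic id.  Unique-best assignment (rather than
any-overlap multi-counting) prevents double-counting where hairpin arms
or neighbouring features overlap; setting `min_overlap_frac` near 1/readlen
approximates any-overlap counting.  Library size = assigned reads;
filtering features never rewrites library sizes, so RPM is stable under
filtering.  The low-count rule retains a miRNA whose replicate-mean raw
count reaches 50 in at least one condition of the comparison scope (the
contrast's two conditions for pairwise DE; any condition for the time
course).

## Consensus differential expression

Two NB tests per contrast stand in for the "called by both programmes"
agreement rule of an edgeR + DESeq analysis:

- **Conditional exact test.** Counts are scaled to the geometric-mean
  library size (pseudo-counts) and summed per group.  The sum of n i.i.d.
  NB(μ, φ) variables is NB with size n/φ; when both groups share μ and φ,
  the group-A sum given the total T is BetaBinomial(T, n_A/φ, n_B/φ).  The
  two-sided p-value sums the probabilities of all splits as or less likely
  than observed (ties included at 10⁻⁹ relative tolerance).  At φ = 0 this
  is the conditional binomial (Poisson) test.  The pmf is evaluated in log
  space from cumulative-log tables, so a contrast over thousands of
  features at 2×10⁶ depth runs in seconds.
- **Wald test.** z = Δlog(mean)/SE with the delta-method SE from
  Var(x) = μ/s + φμ² on size-factor-normalized counts; two-sided normal
  p-value; p = 1 when both groups are all-zero.

Dispersion is method-of-moments per feature — (var − mean/s̄)/mean² within
each replicated condition, df-weighted — shrunk 50/50 toward the 20 %
trimmed-mean common dispersion and floored at 10⁻⁴.  Size factors are
library sizes scaled to geometric mean 1 (RPM-consistent; median-of-ratios
is deliberately not used because miRNA libraries are dominated by few
features).

A miRNA is DE when both BH-adjusted p-values are ≤ 0.05 (inclusive) and
|log₂FC| ≥ 1.5 (inclusive), with the fold-change stabilized by a 0.5
pseudo-count on normalized means.  Only count-filter-passing features are
tested, and BH runs across tested features.

**Levelling classification.**  Per strain pair: class #1 = DE at control
and not DE at any levelling-window timepoint (default {1 h}; the window is
configurable because the 6 h point also shows the uniform pattern);
class #2 = not DE at control and DE at ≥ 1 recovery point.  Class #1 takes
precedence when both patterns occur across different pairs.  The
common/shared/unique group comes from the supporting pairs: all pairs →
common; two pairs sharing a hub strain → unique to that hub (it is the
strain that deviated at control); a single pair → shared by those two
strains.  The levelling index — the mean over miRNAs of the maximal
pairwise |log₂ RPM difference| of strain means at a timepoint —
summarizes the contraction of interstrain spread after heat shock.

## Time-course selection

Profiles: replicate-mean RPM → log₂(RPM + 1) → z-scale with the mean/SD of
the miRNA's full profile (strains × timepoints pooled; pooling is the
pinned choice so strain offsets survive scaling) → subtract each strain's
control value so every profile starts at 0.  Zero-variance profiles are
set to all-zero and flagged.  The same scaling constants and anchors are
applied to each replicate; the regression fits these replicate-level
observations (each library is an observation, as in array-style
time-course modelling) — fitting replicate means would leave only 3
residual df for the 9-parameter full model and no usable power at 2
replicates.

Full model per miRNA: intercept, t and t² in actual hours (degree 2 is the
highest degree leaving residual df at 4 timepoints), dummies for non-
reference strains, and dummy × time interactions.  Selection path: global
F-test (full vs intercept) → BH across miRNAs (Q ≤ 0.05) → backward
stepwise at α = 0.05 (drop the worst p > α each round; ties drop the
higher polynomial order, then the later column) → R² of the selected model
≥ 0.6.  The procedure rotates the reference strain; a strain's verdict is
read from the rotation in which it is the reference, where the pure time
terms carry its own temporal profile.  (A strain's dummy terms in other
rotations measure level differences from the reference, not temporal
change; flagging on them would mark every strain whenever any one
deviates.)  Rank-deficient designs drop aliased columns with a warning.

## Y^S1 distance and clustering

d(x, y) = 1 − (ρ* + A + M)/3 with ρ* = (Spearman ρ + 1)/2 (0.5 for a
constant profile, flagged), A the fraction of adjacent intervals whose
slope signs agree (zero slope is its own sign), and M the mean of the
argmax- and argmin-position agreement indicators (first occurrence on
ties).  Equal weights are the package's pinned parameterization; all three
weights are configurable.  Multi-strain items use the mean of per-strain
distance matrices.  Clustering is complete-linkage agglomeration on the
distance matrix cut into k = 6 clusters (matching the six observed profile
groups; k is configurable and no automatic selection is attempted), with
items sorted lexicographically beforehand and cluster ids renumbered by
smallest member so results are order-independent.  Cluster mean profiles
are OLS lines per strain over member values with the pointwise 95 % CI of
the mean response.

## Arm switching and editing

The arm ratio is log₂((mean5p + 0.5)/(mean3p + 0.5)); its sign marks the
dominant arm.  An event between control and a recovery point requires
|Δratio| ≥ 1 (inclusive) and either a dominant-arm sign flip or the minor
arm rising through the count floor (default 50), and both arms must reach
the floor in at least one of the two conditions.  The statistic is
invariant to joint library rescaling.

Editing calls use a mismatch-frequency rule on strand-resolved pileups:
all bases are read on the mature sense strand, and a site is called when
coverage ≥ 10, the substitution frequency ≥ 0.1 and the substitution is
A→G or T→C (the ADAR signature and its antisense mirror).  The seed region
is pinned to mature positions 2–8.  No frequency test gates the calls; a
binomial tail probability against the background error rate is emitted as
metadata only.  At the default thresholds a single mismatched read at
coverage 10 reaches frequency 0.1, so sparse false sites can appear in
low-coverage libraries — raising `min_cov` suppresses them; the benchmark
conditions (coverage ≥ 100) make false calls against a 10⁻³ error rate
essentially impossible.

## Targets, ontology, semantic similarity

Consensus targets keep edges supported by ≥ 2 prediction algorithms
(duplicates within one algorithm are deduplicated with a warning).  Group
target sets keep only genes unique to one miRNA group across all groups.
GO enrichment is the one-sided hypergeometric test per term; the elim
variant processes terms by decreasing longest-path-from-root level and,
when a term reaches p ≤ 0.05, removes its study∩annotated genes from every
ancestor's current annotation before the ancestor is tested.  (This
removes study genes only — a deliberate, pinned simplification of the
original elim, which removes the genes from the population side as well.)
With elim_alpha = 0 no elimination happens and the result equals plain
Fisher.  An optional evidence-code filter and a labelled, non-equivalent
ancestor-collapse redundancy filter are input-side conveniences.

Semantic similarity uses the Wang graph measure: S-values decay 0.8 per
is_a hop along the term's ancestor closure, a term pair scores
Σ(S₁+S₂ over shared ancestors)/(SV₁+SV₂), and sets combine by best-match
average.  A Resnik variant (normalized max-IC of common ancestors, IC from
annotation frequencies) is available behind a flag.  Significance is the
plain frequency of n = 500 uniformly sampled same-size term-set pairs
scoring ≥ the observed value — this estimator can return exactly 0, which
is kept as the default for fidelity; an (x+1)/(n+1) correction is opt-in.
Null sampling is uniform over all DAG terms, without stratification.

## Reproducibility and problem sizes

Every stochastic step derives from one mandatory seed via numpy
`SeedSequence` substreams, and set-valued intermediates are iterated in
sorted order, so identical configurations give byte-identical outputs
across processes.  The default pipeline simulates 120 hairpins at 50 k
reads/library (24 libraries) — sizes chosen so a complete run stays
interactive on a laptop while every stage still has signal to find;
the calibration benchmarks run at the full 2×10⁶-read depth.  The test
suite checks the exact test against direct conditional enumeration, the
counting and Venn logic against brute-force oracles, the full selection
path against an independent statsmodels reimplementation, the Wang measure
against hand-evaluated toys, and the calibration/recovery rates quoted in
the README; `scripts/acceptance.py` recomputes all of those from scratch.

## Known limitations

- The exact test conditions on pseudo-count totals after rounding; with
  strongly unequal library sizes this is an approximation (as in the
  quantile-adjustment it imitates).
- Dispersion shrinkage is a fixed 50/50 blend, not an empirical-Bayes
  weight; it is adequate for calibration at the benchmark's replication
  levels but less efficient than edgeR's.
- The Y^S1 components are coarse on 4-point profiles (3 slope signs, one
  extremum pair); clusters separated only by amplitude are not
  distinguishable by design.
- isomiR-level resolution, FASTQ qualities, SAM/BAM input and real
  database integrations are out of scope.
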