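# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the design choices made where the design was genuinely open.

## Coordinates and interval algebra

All genomic coordinates are 0-based, half-open (BED convention); every
reader and writer assumes it. Three primitives underlie the landscape
construction:

* `merge_intervals(ivs, gap)` bridges separations ≤ `gap` (150 bp for
  CUT&RUN peak sets; 0 for plain unions). Adjacency (separation 0) always
  merges; a 151-bp separation at `gap=150` does not.
* `reproducible_peaks(sets, m)` binarises each replicate's coverage,
  thresholds the per-base replicate-depth profile at `m`, and segments.
  This is symmetric in replicate order, unlike anchoring on one
  replicate's peaks, which is why it was chosen over an intersect-style
  formulation: the result cannot depend on which replicate is listed
  first. `m=1` provably equals merging the concatenation with gap 0, and
  the retained base set is monotone decreasing in `m`. Typical settings:
  5-of-8 for cut-site peak sets, 4-of-5 or 3-of-3 for binding factors.
* `summit_window(iv, track, hw)` returns `[summit−hw, summit+hw)` where
  the summit is the **leftmost** argmax of the signal inside the interval
  (deterministic tie-break). All-zero signal falls back to the interval
  midpoint and is flagged; windows are clipped at chromosome boundaries
  and flagged, never dropped. "Extended 500 bp from the summit" is read as
  ±500 bp, giving 1,000-bp windows.

The landscape is the merged union of reproducible accessibility and
H3K27ac regions (concatenated over time points), optionally minus a
user-supplied blacklist (subtracted from the union, before windows are
formed), reduced to fixed-width accessibility-summit windows; each element
records whether it came from accessibility, acetylation, or both. Binding
peak sets used for overlap flags follow the factor-specific conventions
(±500 bp around maxima for the activity-inducible bHLH–PAS factor, i.e.
1-kb peaks; ±200 bp for other factors), configurable at the call site.

All three primitives are validated against an explicit per-base depth-array
oracle on 1,000 random ≤10-kb instances (exact equality).

## UMI consensus and mutation frequency

Reads are assumed pre-aligned to their amplicon reference (the generator
emits aligned calls; realignment is out of scope). Families are exact-match
groups on (amplicon, 12-nt UMI); no edit-distance collapsing is performed
because the 4¹² UMI space vastly exceeds template counts at assay scale and
exact grouping is deterministic — near-duplicate UMIs (Hamming 1) are
tallied in a QC report instead. UMIs containing N are discarded and
counted.

A family of size ≥ `min_depth` (default 10) contributes one count at every
position where **all** its members make the identical call — unanimity
across all reads, not a subsample of 10, which is stricter and
deterministic. Insertions are anchored to the reference position
immediately left of the inserted bases and are unanimous only when every
member carries the identical sequence at the identical anchor; at each
position the reference/substitution/deletion counts partition the unanimous
family count, with insertions counted on top (they do not displace the base
call at the anchor). Amplicons are kept when the mean unanimous-family
depth over non-primer positions strictly exceeds `min_mean_depth` (default
100).

Frequencies: `f_total` divides mutated families (substitutions + indels)
by total consensus bases over assessed positions (positions 23+, 1-based;
the 22-bp primer region is excluded from numerator and denominator). A
zero denominator yields a missing value, never zero — missing frequencies
are excluded from medians and outlier tests throughout. Collapsed
substitution classes pool complementary changes (strand of origin is
unknowable); each class divides by the consensus depth over positions whose
reference base belongs to the pair. Age normalization divides each
animal's per-site frequency by the site's median over young animals
(even-count medians are the mean of the central pair); the young median of
normalized values is therefore exactly 1 per site when the young count is
odd.

**Error suppression.** With independent per-base read error rate e
(uniform over the three alternatives), a size-k family is unanimously wrong
at a position with probability 3·(e/3)^k. At e=0.005, k=10 this is
~4·10⁻²⁵; the mutation-free simulation (30 amplicons × 100 assessed bp,
≥200 qualifying families per site) must measure a false-substitution rate
≤ 10× this bound, i.e. zero observed false families.

**ROUT outliers.** The robust outlier test is specialised to a location
model: centre = median, robust scale = 68.27th percentile of absolute
residuals × n/(n−1), per-point t-ratios on n−1 df, Benjamini–Hochberg
step-up at Q (default 0.001). The originating implementation is
proprietary, so this recipe is frozen as the package's reference behaviour
and property-tested: ≤0.5% false flags on clean Gaussians at Q=0.1%, ≥99%
detection of a 10-robust-scale outlier. It is applied identically to
normalized and raw frequency series.

## Break counting and normalization

Unique break events are distinct (chrom, pos, strand, UMI) tuples; strand
is part of the key by default (two opposing free ends at one bp are
distinct ligation events) and can be dropped via `use_strand=False` since
upstream conventions differ. Only the single-bp cut end is counted against
elements (`start ≤ pos < end`); overlapping summit windows each count a
shared event, which is documented behaviour rather than an error.
Genome-wide totals downsample **reads** (pre-dedup records, matching how
sequencing depth is equalised) to the minimum depth, without replacement,
seeded, then dedup and count.

Size factors are median-of-ratios: per sample, the median over
all-samples-positive elements of count/row-geometric-mean, rescaled to unit
geometric mean (cross-checked in the tests against an independent
median-of-ratios implementation, pydeseq2, to 10⁻¹⁰). Low-count filters
follow the two assay conventions: ≥2 non-zero samples for
accessibility/acetylation/damage marks, ≥1 for the sparser cut-site data.
Per-genotype contrasts (Cre vs ΔCre) are normalized within genotype by
running `size_factors` on each genotype's columns.

Batch adjustment fits, per element, an additive condition+batch linear
model on log2(normalized+1) by least squares and subtracts the fitted batch
terms centred so that batch effects sum to zero weighted by batch sizes
(condition contrasts are unchanged; the operation is idempotent; confounded
designs are rejected by a rank check).

**Inducible calls.** The null H0: log2 fold change ≤ log2(threshold) is
tested one-sided per element on log2(normalized+1) replicate values with
the threshold as offset, BH-adjusted across all filtered elements per
assay; an element is inducible iff the realised fold change meets the
threshold AND adjusted p < 0.05 (strict exceedance: an exactly-2-fold
change with tight replicates is not called). Landscape inducibility is the
OR-union over assays (2× accessibility, 1.5× acetylation). One-sided
testing was an open choice; increases define inducibility, so only the
increase direction is tested.

The per-element variance is shrunk toward a prior fitted across all
elements (empirical Bayes: scaled inverse-chi-square prior estimated by
moment matching on log s², posterior df d0+d). This replaces the
negative-binomial Wald machinery of count-model packages with a
deterministic, dependency-free equivalent of their key ingredient —
information sharing across elements. A plain per-element Welch t
(`moderation=False`) has essentially no power against an offset null at
2–3 replicates per group (measured sensitivity 0.02 under the validation
conditions below, vs 0.94 with moderation); the substitution is validated
by type-I and power simulation rather than by matching any external tool's
output: boundary-null type-I ≤ α + 3·SE over 2,000 elements, and planted
4-fold increases (3v3, CV 20%, 1,000 null elements) recovered with
sensitivity ≥ 0.9 at empirical FDR ≤ 0.1.

**Quartile stratification.** Elements are ranked by (binding sum)/(control
sum + ε) with ε = 1 read-depth unit (zero-control elements are still
ranked, flagged), sorted stably by (ratio, chrom, start), and cut into four
equal-count bins (sizes differ by ≤1). Q4-high additionally requires
overlap with a called binding peak; Q1-low requires its absence.

## The resampling null

The observed statistic is the mean over target genes of the per-gene
(mean ΔCre − mean Cre) difference within a cell type, computed on
normalized expression values (the plotted quantity; pseudobulk summing was
the alternative and is not used). The null resamples `n_targets` genes
without replacement from the top ⌈10%⌉ of genes by mean expression across
all nuclei of the cell type, infection status ignored (a symmetric choice;
the assignment itself is made beforehand from viral counts with the strict
\>8-transcript rule, double-positives excluded as ambiguous). Because the
statistic is linear in per-gene group means, resampling precomputed
per-gene differences is exact. The +1-corrected empirical p is never zero;
its floor at 10,000 iterations is 1/10,001 ≈ 10⁻⁴, which is what a planted
knockdown far outside the null should produce. Calibration: with targets
drawn from the pool itself, empirical p is uniform (KS p > 0.01 over 500
seeded repetitions at n_iter = 2,000).

## Synthetic generators

Every generator is a pure function of (config, seed) and emits truth tables
sufficient to score downstream stages. Defaults are desk scale: 2
chromosomes × 1 Mb, 200 elements of 1 kb, 30 amplicons of 122 bp (22-bp
primer + 100 assessed).

* **Amplicons** — templates per site (default 400; 700 in the recovery
  simulations, giving >5·10⁴ consensus bases per replicate) mutate
  independently per assessed position at the site's true frequency
  (mutation shared by the whole family; 5% of planted events are
  deletions); family sizes are zero-truncated Poisson(λ=12) (a
  negative-binomial alternative is in the config since real family sizes
  are overdispersed); reads add independent per-base errors at e = 0.005.
  The ageing cohort multiplies a young frequency of 5·10⁻⁴ by (1, 2, 3)
  across young/middle/old at unbound sites and by a damped (1, 1.2, 1.4)
  at TF-bound sites, 5 animals per group.
* **Cut sites** — per element and sample, unique events are
  Poisson(rate·width·fold) with rate 0.05/bp (~50 events per element, the
  depth of a ~10M-read library over a ~2·10⁵-element landscape); fold
  applies to truth-inducible elements, interpolating the condition profile
  (1, 3, 1.5, 3) over (0 h, 2 h, 10 h-less-active, 10 h-still-active) by
  binding-quartile weight (0, 0.25, 0.5, 1). Each event is re-read
  1+Geometric(p=0.5) times (PCR duplicates); background events scatter
  genome-wide at 2·10⁻⁴/bp; the second half of replicates forms a batch
  with a 1.5× depth multiplier, all conditions present in each batch.
* **Binding tracks** — per-element log-normal intensity (heavy-tailed)
  with a 2× summit run 50 bp wide; flat control at 1 ± 10% noise; elements
  above the 75th intensity percentile carry a true peak, recovered per
  replicate with probability 0.7 (so 5-of-8 survival tracks the binomial
  tail P(X≥5) ≈ 0.81).
* **Expression** — log-normal gene baselines, per-nucleus gamma noise
  (shape 5) around the baseline; 25 targets drawn from the top decile and
  multiplied by 0.5 in Cre nuclei; viral counts Poisson(30) for the
  carried virus with 10% dropout, Poisson(0.3) background for the other.

What the generators do **not** emulate: read-level sequence artefacts
(quality strings, adapters, chimeras), alignment error, UMI collision
networks and polymerase jackpots, chromatin-driven non-uniform background,
mitochondrial contamination, and real single-cell count sparsity (the
expression matrix is continuous, mimicking already-normalized values).
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated generative assumptions, not
robustness to upstream artefacts in real libraries.

## Numerical conventions

Medians of even counts are the mean of the central pair everywhere.
Quartile and summit ties break deterministically (stable sort; leftmost).
The inducibility test floors zero replicate variance at 10⁻⁸ and the
quartile ratio floors the control denominator at ε=1. Degenerate inputs
fail loudly: malformed intervals name the offending record, confounded
batch designs are rejected, zero-read samples refuse downsampling, and a
count matrix with no all-positive row asks for a pseudo-reference rather
than silently guessing.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use: 30×100 bp
mutation-free amplicons with ≥200 families/site (error suppression); 200
replicates × 7·10⁴ consensus bases at μ ∈ {5·10⁻⁴, 2·10⁻³} (recovery);
1,000 Gaussian samples of n=50 (ROUT); 1,000 random interval instances on
10-kb chromosomes; 2,000 boundary-null and 3×1,100 planted elements
(inducibility); 40 seeded runs of an 80-element time course and of the
1.3× genome-wide contrast; 500 calibration repetitions at n_iter=2,000
plus one planted run at n_iter=10⁴ (resampling). These sizes give binomial
standard errors comfortably inside each stated tolerance.
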