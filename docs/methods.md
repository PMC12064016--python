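# Methods

This note records the statistical procedures `xconcord` implements, the
modelling assumptions behind the synthetic data generator, and the numerical
conventions that affect results.

## The analysis problem

Two platforms measure the same genes in the same cell lines: a targeted
assay reporting probe-level counts with technical replicates, and a
whole-transcriptome reference distributed as replicate-averaged
expression-per-million (EPM; counts-per-million and transcripts-per-million
are treated as directly comparable after both are rescaled to 10⁶ per
sample, which is justified for targeted assays because a single ligation
site per gene removes the gene-length dependence). The pipeline asks three
questions: (i) how reproducible is each platform internally, (ii) how much
of the joint multivariate variance does the platform factor explain, and
(iii) which individual genes disagree enough to drive that divergence, and
does removing or re-normalizing them resolve it.

## Normalization chain

* **Probe collapse.** A gene measured by several probes receives the
  per-sample *maximum* probe count. Ties need no rule; all-zero genes are
  kept at 0.
* **EPM.** Each sample column is rescaled to a total of 10⁶ (tolerance
  0.01). Re-applied after any gene-subsetting step (platform intersection)
  so both platforms stay on a per-million scale over the *shared* genes.
* **log₂(EPM+1).** The +1 pseudo-count maps zero expression to zero. It
  also compresses differences for genes whose effective EPM is near 1 —
  relevant when interpreting planted-bias recovery (below).
* **Replicate averaging.** Arithmetic mean of EPM per gene over replicate
  groups; every replicate carries equal weight, so when two acquisition
  phases are pooled a cell line's mean is the mean of all six replicates
  (equal to the mean of phase means only for balanced designs).

## Variance attribution

PCA follows the usual convention: samples are observations, the data are
centered but not scaled (both platforms are already on equivalent units),
eigenvalues are `s²/(n−1)` from the SVD, and at most `n−1` components are
kept. Sequential (Type-I) ANOVA on a PC score vector and PERMANOVA on a
distance matrix share one code path: nested dummy-coded designs with
intercept give projectors `H_0 ⊂ H_1 ⊂ …`, and term k's sum of squares is
`tr(H_k G) − tr(H_{k−1} G)` with `G` either the outer product of the
centered scores (ANOVA) or the Gower-centered `C(−½ D∘D)C` (PERMANOVA).
R² = SS/SS_total is permutation-free; the permutation p-value
`(1 + #{F* ≥ F}) / (n_perm + 1)` uses free whole-row label permutation (no
strata), 999 permutations by default. Because Euclidean distances on
centered data coincide with distances on the full PCA scores, "PERMANOVA on
the PC distance matrix" and "PERMANOVA on the data" are the same analysis;
the test suite asserts this isometry to 1e-8.

The dispersion test embeds samples by PCoA (real and imaginary axes kept
separately; for Euclidean input the imaginary part is empty), measures each
sample's distance to its group center, and compares groups with a
parametric one-way F. The center is the **centroid** by default —
deterministic and closed-form; a spatial-median variant (Weiszfeld
iteration on the real axes) is exposed because reference implementations
default differently. Groups of size one get distance 0 and are flagged. An
optional permutation p re-labels samples and recomputes the full statistic.

## Non-concordant gene determination

On replicate-averaged, harmonized matrices (one column per cell line), the
per-gene difference is Δ(g,c) = log₂(EPM_T+1) − log₂(EPM_R+1). The
procedure iterates symmetric percentile pairs (10,90), (11,89), …:

1. per-cell-line percentiles of Δ (linear-interpolation quantiles — the
   convention matters: cutoff values shift slightly across conventions) are
   averaged across cell lines into a cutoff pair (lo, hi);
2. genes passing the expression gate (cross-cell-line mean EPM ≥ 5 on
   *either* platform; genes below it on both are "effectively concordant" —
   the platforms agree they are unexpressed) whose per-gene mean Δ falls
   strictly outside [lo, hi] are marked for removal;
3. PERMANOVA (~platform) on Euclidean distances of the retained-gene log₂
   matrix gives the platform R²; the loop stops at the first pair below the
   target (default 0.10) and fails loudly, with the full trace attached, if
   the pair (49,51) is reached without success.

Percentile scope defaults to **all genes** (matching the ≈20%-of-universe
tail arithmetic of the Δ boxplot distributions); an expressed-genes-only
scope is exposed as an option. The removal statistic is the per-gene mean Δ
across cell lines; strict inequalities are used at the cutoff boundaries.
Inside the loop the PERMANOVA runs without permutations (R² is
deterministic); the final model is refitted with the configured permutation
count for its p-value.

Summaries reported alongside: the mean over cell lines of the per-cell-line
median Δ; per-cell-line quartiles/IQR (cell lines are rankable by IQR); the
mean fold difference defined as the mean of 2^|Δ| per (gene, cell line)
observation with a 95% t-interval, direction reported separately as the
sign of mean Δ (the fold-difference formula is an interpretive choice; the
per-observation mean of 2^|Δ| was selected and is cross-checked against the
folded-normal closed form in the tests); and counts of genes above caller-
supplied |Δ| thresholds with optional gene-list overlap tallies.

## RLE platform correction

Here RLE is a *ratio*, not the conventional subtract-the-reference log
difference: RLE(g,c) = log₂(EPM(g,c)+1) / mean_c′ log₂(EPM(g,c′)+1), the
denominator computed within platform. A per-gene platform scale factor on
the log₂ scale cancels identically, which is exactly the planted-bias
structure; a *constant additive* platform shift does not cancel exactly.
0/0 genes (all-zero across cell lines) map to the neutral value 1.0 and are
flagged, keeping the gene universe intact. The ratio transform is
numerically a fixed point (every gene's cross-cell-line mean is exactly 1
after one application), so the unit tag — not arithmetic — guards against
double application. The printed form of the defining equation is ambiguous
between dividing by the mean of log₂(EPM+1) and by the mean of (EPM+1); the
log₂ reading is the default (it is the one that cancels platform scale
factors) and the (EPM+1) variant is available via `denominator="epm1"` for
auditability.

## Gene-set concordance enrichment

The expressed universe (gate survivors, minus low-expression genes) is
partitioned into non-concordant and concordant; for each signature,
a = signature ∩ non-concordant, b = non-concordant − a, c = signature ∩
concordant, d = concordant − c, OR = (a/b)/(c/d). Counting is
universe-intersected (forced by the margin identity a+c = signature genes
in the analysis). Zero cells: OR = +∞ when only b·c = 0, 0 when only
a·d = 0, undefined when both; a Haldane–Anscombe (+0.5) OR is carried for
ranking, and 1/OR is reported for OR < 1. The significance test is
two-sided Fisher exact (the natural exact test for a 2×2 with fixed
margins; a chi-square variant is exposed). BH-FDR is computed over the
signatures passing the inclusion criteria (≥ 10 genes in the universe AND
≥ 50% coverage of the signature); excluded signatures keep raw p with NaN
FDR. Coverage percent is rounded half-even to an integer. Gene identity in
this module is symbol-based (GMT files carry symbols); an optional
two-column symbol map harmonizes annotation releases.

## Synthetic data generator

The generator emulates the dual-platform study structure: expected log₂
expression of gene g in cell line c is `baseline(g) + effect(g,c)` on the
reference platform and additionally `+ bias(g)` for planted genes on the
targeted platform. Log₂ values map to relative abundances `w = 2^x − 1`
(so a self-normalized library reproduces log₂(EPM+1) = x up to a per-sample
scale shift), replicates add Gaussian noise on the log₂ scale, and targeted
counts are `rint` of the library-size-scaled abundances (Poisson sampling
optional, off by default — the pipeline operates on log₂(EPM+1), and
log-normal noise is the simplest model that stresses it).

Defaults, chosen once as the study conditions (neither platform's noise
magnitude is published, so these are set for testability at realistic
scale): 2,000 genes; 12 cell lines; 3 technical replicates; 20% of
expressed genes biased with |bias| ~ U(2, 8) log₂, half up / half down; 5%
universally unexpressed; baselines U(0, 12) log₂; cell-line effects
N(0, 1) with a 10% "marker" subset at N(0, 3) so ordination separates cell
lines; replicate noise sd 0.25 log₂; library sizes U(4.5×10⁶, 6×10⁶); up to
3 probes per gene (the first probe carries the gene count, so probe
collapse recovers gene-level counts exactly; other probes draw uniformly in
[0, count]). The reference platform emits one EPM sample per cell line
(public whole-transcriptome compendia distribute replicate-averaged values
only) with a single measurement-noise draw.

**Mass-balanced bias planting.** One-sided large log₂ biases would inflate
the targeted platform's total linear library mass, and per-million
normalization would then shift *every* unbiased gene down — a global
platform offset that per-gene removal provably cannot resolve, and which
the data this generator emulates do not show (their global median shift is
near zero). Biased-gene baselines are therefore drawn so that both the
biased and unbiased values lie inside the global dynamic range (up-biased
genes from the low end, down-biased from the high end), making the added
and removed linear mass cancel in expectation. This requires the maximum
bias not to exceed the baseline range width (validated).

What the generator does **not** model: probe-sequence hybridization
efficiency, GC and gene-length effects, batch structure beyond phase/depth,
count overdispersion beyond the log-normal noise (unless Poisson sampling
is enabled), and correlated gene modules. Passing tests therefore
demonstrate that the *procedures* behave as specified under planted truth —
not that any particular real platform pair will show the same variance
shares.

## Numerical conventions and degenerate inputs

* Quantiles: linear interpolation between order statistics throughout.
* Correlation summaries: mean of raw r values with a 95% t-interval,
  clipped to [−1, 1]; n = 1 gives a point interval. (No Fisher-z transform:
  degenerate intervals like 0.99–0.99 are then representable naturally;
  whether the emulated analysis used Fisher-z is unknown and noted, not
  guessed.)
* Zero-variance samples in correlation: r recorded as NaN and flagged, not
  raised.
* Saturated ANOVA (zero residual df): R² reported, F/p flagged NaN.
  All-coincident points in the dispersion test: F/p NaN.
* PERMANOVA R² = 0 and p = 1 are representable exactly; tiny negative
  round-off in term SS is clamped at zero.
* Permutation p-values use ≥ with a 1e-12 tolerance on the observed F.
* Determinism: every stochastic stage (generator, permutation tests) takes
  an explicit seed; identical inputs and seeds give identical outputs,
  byte-identical for the generator.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
default study scale (2,000 genes × 12 cell lines × 2 platforms, and a
6-cell-line two-phase replicate design), with 999 permutations for reported
p-values and smaller permutation counts inside unit tests where only the
permutation-free R² is asserted. The complete suite runs in well under a
minute on one CPU.
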