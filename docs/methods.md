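# Methods

This note documents the models the package implements, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that affect results.

## Expression trees

**Distance.** For one tissue, the distance between two species is
`d = 1 − ρ` with ρ the Spearman rank correlation of their expression
profiles over the shared single-copy ortholog set (average ranks on ties).
`d ∈ [0, 2]`; because the statistic is rank-based, any strictly monotone
transform of the values (e.g. raw TPM vs log2(TPM+1)) yields a bit-identical
distance matrix — asserted as a property test, which is why no normalization
step is needed before tree building. Constant species profiles make ρ
undefined and are a hard, named error.

**Neighbor joining.** Classic Saitou–Nei agglomeration with the
Studier–Keppler O(n³) criterion `Q(i,j) = (r−2)d(i,j) − R_i − R_j`, closed
with the exact three-taxon formula. Conventions:

- ties in the Q minimization are broken by lexicographic order of the two
  clusters' smallest leaf labels, making the output order-independent and
  deterministic;
- negative edge-length estimates are clamped to 0; the count and the
  pre-clamp values are kept on the result and surfaced with a warning.
  Additive matrices never trigger clamping, and NJ is exact on them
  (topology recovered, path distances reproduced to < 1e-9) — this is the
  main correctness check.

**Total branch length (TBL)** is the sum of all edge lengths of the
unrooted tree, used as a per-tissue divergence statistic; the tissue report
ranks tissues by ascending TBL. Tissues with non-identical taxon sets are
flagged rather than silently intersected.

**Replicates.** The pipeline carries one expression value per species (the
ortholog matrices the analysis consumes are already per-species summaries);
`exprtree.average_replicates` provides the optional pre-averaging step for
matrices with within-species replicate columns. This is an assumption, not
a derivation: with replicates, averaging before the rank correlation is the
package's chosen convention.

## Species-specific expression shifts (ΔAIC)

**Model.** Per gene, log2 expression across the n tips of a rooted species
tree is modeled as multivariate normal with BM covariance
`C[i,j] = shared root-to-tip path length` (units of the tree's branch
lengths, here nucleotide-divergence distance). The null has mean `μ·1`
(k₀ = 2 including σ²); the alternative adds a fixed offset `δ` (log2 units)
on one focal terminal lineage (k₁ = 3). Both are generalized-least-squares
ML fits:

```
β̂ = (XᵀC⁻¹X)⁻¹ XᵀC⁻¹x,   σ̂² = (x − Xβ̂)ᵀC⁻¹(x − Xβ̂)/n,
lnL = −½[n ln(2πσ̂²) + ln|C| + n]
```

ML (not REML) variances are used so that AIC comparisons are coherent.
`ΔAIC = 2(lnL₁ − lnL₀) − 2` is bounded below by −2 for nested ML fits;
floating-point results within 1e-9 below the bound (δ̂ = 0 cases) are
snapped to exactly −2, anything further below raises. The shift model is
one concretization of "variation not explained by evolutionary history";
the fitting surface is per-gene and pluggable, so an OU-type engine could
replace it without touching the resampling or reporting layers.

**Calibration.** Under the null, the GLS likelihood-ratio statistic gives
`ΔAIC > 0 ⇔ F(1, n−2) > (n−2)(e^{2/n} − 1)` exactly; with n = 9 taxa the
expected positive fraction is `P(F(1,7) > 7(e^{2/9}−1)) ≈ 0.228`. The test
suite and the acceptance script verify the simulated null against this
closed form.

**Numerical conventions.** σ̂² is floored at 1e-9 (log2² per unit branch
length) with a degenerate-fit warning; genes hitting the floor (constant
profiles) are excluded from the genome-wide table and listed separately.
The tree must be rooted with strictly positive tip depths; a basal
multifurcation is treated as an unrooted tree and midpoint-rooted first
(computed analytically from path distances, with a warning). `C` is
Cholesky-factorized once per tree and shared across genes.

**Focal species** defaults to pig (the knockout model species); a
`"best"` mode scores each gene by its best single-species shift at the
same parameter count, which inflates ΔAIC by a selection effect and is
provided for exploration, not calibration.

**Spatial neighborhood and resampling null.** "Spatially close" defaults
to genes whose BED interval (0-based, half-open) intersects the focal
interval extended ±1 Mb on the same chromosome — a conventional cis
window; `n_nearest` (midpoint distance, ties by gene id) is the
alternative. The null distribution draws `draw_size = |neighborhood|`
genes without replacement from the pool of all non-focal, non-neighbor
genes genome-wide (10,000 iterations, seeded) and records each draw's
median ΔAIC; drawing within-neighborhood instead is a caller choice of
pool. Neighborhood vs null medians are compared with the Wilcoxon
rank-sum test: exact by enumeration when both samples have n ≤ 12 without
ties, otherwise a tie-corrected normal approximation whose continuity
correction is sign-aware (a statistic exactly at its null mean gives
p = 1). Percentiles are reported as the fraction of reference values
strictly below the focal ΔAIC.

## Kinetics

**Clearance.** `C(t) = b + C₀e^{−kt}` on the standard sampling grid
(0 and 5 min, 1, 4, 12, 24, 48 h); `t½ = ln2/k` in hours. Fits operate on
per-time group means (one curve per group), matching how a single
half-life per genotype is reported. Baseline modes:

- `zero`: b = 0, log-linear least squares on log C — exact on noiseless
  exponentials and the mode that matches series generated without a floor;
- `subtract_t0`: the first sample is read as a pre-injection baseline,
  subtracted, and excluded from the log-linear fit of the excess (on a
  post-injection-peak series this mode correctly refuses with a
  non-positive-values error);
- `free` (default): nonlinear least squares on (C₀, k, b ≥ 0) initialized
  from the log-linear fit; the reported fit never has a worse residual sum
  of squares than its initialization. Free is the default because real
  plasma ApoB has an endogenous floor, but with only seven time points and
  ~1 observed half-life the three-parameter fit is weakly identified — the
  pipeline therefore reports all modes side by side, and the recovery
  study (500 replicates, 2% noise, generating half-life 25.89 h) uses the
  mode matching the generating model, recovering the mean t½ within 5%.

**Secretion.** OLS of plasma TC/TG (mmol/L) on time over the 1–4 h
post-Poloxamer window; slope, standard error and R² from the closed-form
normal equations. Group fits are scale-equivariant: rescaling
concentrations rescales C₀/slope and leaves k and t½ unchanged.

## Lipid panel statistics

Percent difference is `(mean_ref − mean_alt)/mean_ref × 100` with WT as
the reference — "42.51%" reads "the knockout group is 42.51% lower". Fold
change is the ratio of a group's mean at a later timepoint to its mean at
the reference timepoint, taken here as the atherogenic-diet start
(6 months); comparing to age-matched normal-diet controls instead is a
caller choice of panel. Two-group tests are pooled-variance two-sided
Student's t (df = n₁+n₂−2, not Welch); ≥3 groups use one-way ANOVA with
Tukey HSD p-values from the studentized-range distribution (statsmodels).
Degenerate cells are explicit: zero pooled variance with unequal means is
flagged and reported as p → 0; identical groups give t = 0, p = 1. Both
ratio statistics are unit-invariant.

## Synthetic data: what it does and does not emulate

The default phylogeny is a balanced 9-mammal tree (human, macaque, mouse,
rat, rabbit, pig, cow, dog, horse) with unit-scale branch lengths, a
stand-in for an unpublished species tree. Expression is simulated directly
on the log2 scale as BM with gene-specific rates σ² ~ U(0.2, 1.0) (log2²
per unit branch length) plus N(0, 0.1²) tip measurement noise — smooth
trait evolution plus i.i.d. noise, which is exactly the downstream model's
assumption. Shifts add a fixed log2 offset (default +2, a 4-fold change)
to the focal species on `round(fraction × n_genes)` genes. The generator
does **not** emulate read-count sampling noise, expression
mean–variance coupling, correlated genes, assay batch effects, or
ortholog-calling errors; passing tests therefore demonstrate correctness
of the computations under their stated model, not robustness of the
biology to real-data violations of it.

Panels draw animal values as N(mean, sd) with cohort sizes mirroring the
in-vivo design (10 WT vs 6 homozygotes, 8 heterozygotes; 3 per group on
the atherogenic diet) and group means anchored so that the 10-month
percent reductions (42.51% non-HDL-C, 46.93% LDL-C, 31.19% TC, 34.06%
VLDL-C, 32.43% TG, 17.72% ApoB; 23.64% non-HDL-C in heterozygotes) and
the diet-response folds (8.25× WT, 2.77× heterozygote) are the exact
sd = 0 outcomes; the default coefficient of variation is 0.15, a typical
between-animal spread for plasma lipids. Clearance series use C₀ = 100
(arbitrary concentration units) with noise_sd = 2 (2% of C₀) in recovery
studies; generating half-lives are anchored at 25.89 h and 39.14 h.

## Problem sizes

Default pipeline runs use 400 genes × 2 tissues, 10,000 resampling
iterations; the verification suite uses 200 random additive matrices
(5–9 taxa), 50 rank-invariance fixtures, 50 grid-oracle problems
(zooming 31-point grids, 18 stages, accurate to ~1e-12 lnL), 2,000 null
genes for ΔAIC calibration, 100 power replicates of 150+150 genes, and
500-replicate kinetics recovery studies. The full synthetic run and the
whole test suite each complete in well under a minute on one CPU.

## Known limitations

- The shift model tests a single pre-specified focal lineage; it does not
  search over shift placements with proper multiplicity control, and no
  per-gene significance calls or multiple-testing corrections are made
  (distributions are the object of interest).
- TBL comparisons across tissues assume a common taxon set; mismatches
  are flagged, not reconciled.
- The free-baseline clearance fit is weakly identified on seven time
  points (see above); half-lives from different baseline conventions can
  differ by several hours on noisy series.
- Wilcoxon p-values on the normal path are approximate for small samples
  with ties; the exact path covers the no-tie n ≤ 12 regime.
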