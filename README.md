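# expevo

Cross-species expression phylogenetics and in-vivo lipid statistics for a
pig knockout-model study design, with a synthetic-data generator so every
stage runs and is testable without any downloads.

## The scientific problem

Loss-of-function variants in the hepatic lectin receptor gene *ASGR1*
lower atherogenic non-HDL cholesterol. Characterizing a knockout animal
model of this effect takes two kinds of computation that this package
implements end to end:

1. **Expression phylogenetics.** How conserved is a tissue's
   transcriptional output across mammals, and does a particular gene show
   species-specific expression shifts? For each tissue, pairwise distances
   between species are `d = 1 − ρ` (Spearman's rank correlation over a set
   of single-copy orthologs), a neighbor-joining (NJ) tree is built from
   the distance matrix, and the tree's **total branch length (TBL)**
   summarizes expression divergence. Per gene, two Gaussian models of
   log2 expression `x` across the `n` species of a phylogeny with
   Brownian-motion (BM) tip covariance `C` are fit by maximum likelihood:

   - null: `x ~ N(μ·1, σ²C)` (k₀ = 2 parameters),
   - shift: `x ~ N(μ·1 + δ·e_focal, σ²C)` (k₁ = 3), where `δ` is an
     expression offset on one focal terminal lineage,

   and compared by `ΔAIC = AIC₀ − AIC₁ = 2(lnL₁ − lnL₀) − 2 ≥ −2`. Larger
   ΔAIC means stronger species-specific divergence. A focal gene's ΔAIC is
   placed in genomic context by drawing same-size gene sets from a pool,
   taking each draw's median ΔAIC (10,000 iterations), and comparing
   distributions with the Wilcoxon rank-sum test.

2. **Lipoprotein kinetics and longitudinal lipid statistics.** Clearance
   of injected ApoB-containing LDL is fit as first-order decay
   `C(t) = b + C₀e^(−kt)` with half-life `t½ = ln2/k`; hepatic VLDL
   secretion after lipase inhibition (Poloxamer-407) is the OLS slope of
   plasma TC/TG over 1–4 h. Longitudinal lipid panels are compared by
   group percent difference `(mean_ref − mean_alt)/mean_ref × 100`, fold
   change between timepoints, pooled-variance Student's t, and one-way
   ANOVA with Tukey's HSD.

The synthetic generators produce inputs with exactly the structure these
analyses assume (BM-evolving log2 expression on a 9-mammal tree with
optional injected shifts, gene coordinates with spatial neighborhoods,
group-structured panels, exponential/linear kinetics series), so every
downstream claim is checked against known ground truth.

## Worked example

```python
import expevo
from expevo.synthetic import default_tree, ShiftSpec, simulate_clearance_series, half_life_to_rate

tree = default_tree()
matrix, truth = expevo.simulate_expression(
    tree, 500, sigma2_range=(0.2, 0.6), noise_sd=0.1, seed=1,
    shifts=ShiftSpec("pig", 0.10, 2.0),          # 10% of genes shifted by +2 log2 units in pig
)
result = expevo.neighbor_joining(expevo.distance_matrix(matrix))
print(f"total branch length: {result.total_branch_length:.4f}")

daic = expevo.genomewide_delta_aic(matrix, tree, focal_species="pig")
merged = daic.table.merge(truth, on="gene_id")
print(f"median dAIC, shifted genes:   {merged.loc[merged.shifted, 'delta_aic'].median():.2f}")
print(f"median dAIC, unshifted genes: {merged.loc[~merged.shifted, 'delta_aic'].median():.2f}")

series = simulate_clearance_series(C0=100.0, k=half_life_to_rate(25.89),
                                   noise_sd=2.0, seed=1, group="ASGR1+/-")
fit = expevo.fit_clearance(series, baseline_mode="zero")
print(f"fitted half-life: {fit.half_life_h:.2f} h (R^2 = {fit.r_squared:.3f})")
```

prints

```
total branch length: 0.1673
median dAIC, shifted genes:   14.04
median dAIC, unshifted genes: -1.46
fitted half-life: 25.23 h (R^2 = 0.997)
```

The genes carrying an injected species-specific shift stand far above the
nesting bound of −2 (median ΔAIC ≈ 14), the unshifted genes sit near it,
and the fitted clearance half-life recovers the generating 25.89 h within
the noise of a single simulated series.

## Command line

```sh
expevo all --seed 1 --outdir run/        # simulate -> trees -> shift test -> kinetics -> lipids
expevo exprtree --matrix run/expression_liver.tsv --out-tree liver.nwk
expevo kinetics clearance --series run/clearance.csv --baseline free
expevo lipids compare --panel run/panel_standard.csv --analyte non-HDL-C --age 10 --alt "ASGR1-/-"
```

Every run writes a `manifest.json` with per-stage seeds and SHA-256
checksums of all artifacts; identical config + seed reproduces identical
checksums. A JSON config file (same field names as `expevo.RunConfig`)
can replace the flags via `--config`.

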