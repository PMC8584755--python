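"""Species-specific expression shifts: phylogenetic ΔAIC and resampling null.

Per gene, two Gaussian models of log2 expression across species are fit by
maximum likelihood:

* the null: Brownian motion (BM) along the species tree, parameters
  (root mean mu, rate sigma^2), k0 = 2;
* the alternative: BM plus a fixed expression offset delta on one focal
  terminal lineage, parameters (mu, delta, sigma^2), k1 = 3.

Both are generalized-least-squares fits under the BM tip covariance
C[i,j] = shared root-to-tip path length of species i and j, so

    dAIC = AIC0 - AIC1 = 2 (lnL1 - lnL0) - 2  >=  -2,

with equality exactly when the estimated offset is zero.  Larger dAIC means
stronger species-specific expression divergence for that gene.  A gene's
dAIC is put in genomic context by drawing same-size gene sets from a pool,
taking the median dAIC of each draw (the resampling null), and comparing
distributions with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import ExpressionMatrix, GeneAnnotation
from .errors import DegenerateFitWarning, UnrootedTreeWarning, ValidationError

#: Lower floor for the ML variance estimate (log2^2 units per unit branch
#: length); hit only by degenerate (near-constant) genes.
SIGMA2_FLOOR = 1e-9

_LN2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# BM covariance

def bm_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion tip covariance structure of a rooted tree.

    Returns the leaf labels and the matrix C with C[i,j] = branch length
    shared by tips i and j on their root-to-tip paths (their MRCA's depth)
    and C[i,i] = depth of tip i.  A tree with a basal multifurcation is
    treated as unrooted and midpoint-rooted first, with a warning.
    """
    depths: dict[int, float] = {}
    leaf_sets: dict[int, list[int]] = {}
    labels: list[str] = []
    order: dict[str, int] = {}

    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        if edge < 0:
            raise ValidationError("negative branch length")
        depths[id(node)] = (depths[id(parent)] + edge) if parent is not None else 0.0

    for leaf in tree.leaf_node_iter():
        order[leaf.taxon.label] = len(labels)
        labels.append(leaf.taxon.label)

    n = len(labels)
    C = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = order[node.taxon.label]
            C[i, i] = depths[id(node)]
            leaf_sets[id(node)] = [i]
        else:
            children = node.child_nodes()
            sets = [leaf_sets[id(c)] for c in children]
            depth = depths[id(node)]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        for j in sets[b]:
                            C[i, j] = C[j, i] = depth
            leaf_sets[id(node)] = [i for s in sets for i in s]

    if len(tree.seed_node.child_nodes()) != 2:
        warnings.warn(
            "unrooted tree (basal multifurcation) midpoint-rooted before "
            "Brownian-motion covariance",
            UnrootedTreeWarning,
            stacklevel=2,
        )
        C = _reroot_covariance_at_midpoint(C)
    return labels, C


def _reroot_covariance_at_midpoint(C: np.ndarray) -> np.ndarray:
    """Recompute tip covariances with the root moved to the tree midpoint.

    Works purely on path distances: D[i,j] = C[i,i] + C[j,j] - 2 C[i,j] is
    rooting-invariant; the midpoint m lies halfway along the longest leaf
    path (a, b), depths become d(m, x), and the shared path length of (i, j)
    from m is (d(m,i) + d(m,j) - D[i,j]) / 2.
    """
    depth = np.diag(C)
    D = depth[:, None] + depth[None, :] - 2.0 * C
    a, b = np.unravel_index(np.argmax(D), D.shape)
    t = D[a, b] / 2.0
    # distance from a to the junction where each leaf's path leaves path(a,b)
    proj = (D[a, :] + D[a, b] - D[b, :]) / 2.0
    new_depth = np.abs(t - proj) + (D[a, :] - proj)
    new_C = (new_depth[:, None] + new_depth[None, :] - D) / 2.0
    np.fill_diagonal(new_C, new_depth)
    return np.maximum(new_C, 0.0)


@dataclass
class BMContext:
    """Precomputed covariance factorization shared by all genes of a tree."""

    labels: list[str]
    C: np.ndarray
    cho: tuple = field(repr=False, default=None)
    logdet: float = 0.0

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "BMContext":
        labels, C = bm_covariance(tree)
        if np.diag(C).min(initial=np.inf) <= 0:
            raise ValidationError("all tip depths must be strictly positive")
        try:
            cho = linalg.cho_factor(C, lower=True)
        except linalg.LinAlgError as exc:
            raise ValidationError(f"singular BM covariance: {exc}") from exc
        logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        return cls(labels, C, cho, logdet)

    @property
    def n(self) -> int:
        return len(self.labels)

    def solve(self, b: np.ndarray) -> np.ndarray:
        return linalg.cho_solve(self.cho, b)


# ---------------------------------------------------------------------------
# per-gene fits

@dataclass
class BMFit:
    """ML Brownian-motion fit: x ~ N(mu * 1, sigma2 * C)."""

    mu: float
    sigma2: float
    log_likelihood: float
    n: int
    k: int = 2
    degenerate: bool = False


@dataclass
class ShiftFit:
    """ML BM-plus-terminal-shift fit: x ~ N(mu * 1 + delta * e_focal, sigma2 * C)."""

    mu: float
    delta: float
    sigma2: float
    log_likelihood: float
    n: int
    focal_species: str
    se_delta: float
    k: int = 3
    degenerate: bool = False


def _gls_ml(ctx: BMContext, X: np.ndarray, x: np.ndarray, warn: bool = True):
    """GLS maximum likelihood for mean design X under covariance sigma2*C.

    Returns (beta_hat, sigma2_hat, lnL, cov_beta_unit, degenerate) where
    cov_beta_unit = (X' C^-1 X)^-1 (multiply by sigma2 for the variance of
    beta_hat).
    """
    n = ctx.n
    CiX = ctx.solve(X)
    XtCiX = X.T @ CiX
    XtCix = CiX.T @ x
    beta = np.linalg.solve(XtCiX, XtCix)
    resid = x - X @ beta
    quad = float(resid @ ctx.solve(resid))
    sigma2 = quad / n
    degenerate = False
    if sigma2 < SIGMA2_FLOOR:
        sigma2 = SIGMA2_FLOOR
        degenerate = True
        if warn:
            warnings.warn(
                "ML variance floored at 1e-9 (near-constant trait)",
                DegenerateFitWarning,
                stacklevel=3,
            )
    lnl = -0.5 * (n * (_LN2PI + np.log(sigma2)) + ctx.logdet + quad / sigma2)
    return beta, sigma2, float(lnl), np.linalg.inv(XtCiX), degenerate


def _as_trait_vector(ctx: BMContext, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = [sp for sp in ctx.labels if sp not in trait.index]
        if missing:
            raise ValidationError(f"trait missing species {missing}")
        return trait.loc[ctx.labels].to_numpy(dtype=float)
    if isinstance(trait, dict):
        return _as_trait_vector(ctx, pd.Series(trait))
    arr = np.asarray(trait, dtype=float)
    if arr.shape != (ctx.n,):
        raise ValidationError("trait length does not match number of tips")
    return arr


def _context(tree_or_ctx) -> BMContext:
    if isinstance(tree_or_ctx, BMContext):
        return tree_or_ctx
    return BMContext.from_tree(tree_or_ctx)


def fit_bm(tree_or_ctx, trait, warn: bool = True) -> BMFit:
    """ML fit of plain Brownian motion to one gene's tip values."""
    ctx = _context(tree_or_ctx)
    if ctx.n < 3:
        raise ValidationError("need at least 3 tips")
    x = _as_trait_vector(ctx, trait)
    X = np.ones((ctx.n, 1))
    beta, sigma2, lnl, _, degenerate = _gls_ml(ctx, X, x, warn=warn)
    return BMFit(mu=float(beta[0]), sigma2=sigma2, log_likelihood=lnl,
                 n=ctx.n, degenerate=degenerate)


def fit_shift(tree_or_ctx, trait, focal: str, warn: bool = True) -> ShiftFit:
    """ML fit of BM plus a fixed offset on the focal terminal lineage."""
    ctx = _context(tree_or_ctx)
    if ctx.n < 3:
        raise ValidationError("need at least 3 tips")
    if focal not in ctx.labels:
        raise ValidationError(f"focal species {focal!r} is not a tip")
    x = _as_trait_vector(ctx, trait)
    X = np.ones((ctx.n, 2))
    X[:, 1] = 0.0
    X[ctx.labels.index(focal), 1] = 1.0
    beta, sigma2, lnl, cov_unit, degenerate = _gls_ml(ctx, X, x, warn=warn)
    se_delta = float(np.sqrt(sigma2 * cov_unit[1, 1]))
    return ShiftFit(mu=float(beta[0]), delta=float(beta[1]), sigma2=sigma2,
                    log_likelihood=lnl, n=ctx.n, focal_species=focal,
                    se_delta=se_delta, degenerate=degenerate)


# ---------------------------------------------------------------------------
# dAIC

@dataclass
class DeltaAICRecord:
    """AIC comparison of the shift model against plain BM for one gene."""

    gene_id: str | None
    lnl0: float
    lnl1: float
    aic0: float
    aic1: float
    delta_aic: float
    delta_hat: float
    se_delta: float
    focal_species: str


def delta_aic(fit0: BMFit, fit1: ShiftFit, gene_id: str | None = None) -> DeltaAICRecord:
    """dAIC = AIC0 - AIC1 = 2 (lnL1 - lnL0) - 2; bounded below by -2.

    The bound holds because the models are nested and both are ML fits;
    values within 1e-9 below -2 (floating-point noise when delta_hat = 0)
    are snapped to exactly -2.
    """
    if fit0.n != fit1.n:
        raise ValidationError("fits are not on the same problem (tip counts differ)")
    aic0 = 2.0 * fit0.k - 2.0 * fit0.log_likelihood
    aic1 = 2.0 * fit1.k - 2.0 * fit1.log_likelihood
    d = aic0 - aic1
    if d < -2.0:
        if d < -2.0 - 1e-9:
            raise ValidationError(
                f"dAIC {d} below the nested-model bound -2; inconsistent fits"
            )
        d = -2.0
    return DeltaAICRecord(gene_id=gene_id, lnl0=fit0.log_likelihood,
                          lnl1=fit1.log_likelihood, aic0=aic0, aic1=aic1,
                          delta_aic=d, delta_hat=fit1.delta,
                          se_delta=fit1.se_delta, focal_species=fit1.focal_species)


@dataclass
class DeltaAICResult:
    """Genome-wide dAIC table plus the genes flagged as degenerate."""

    table: pd.DataFrame
    degenerate_genes: list[str]
    focal_species: str

    def quantiles(self, q=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.Series:
        return self.table["delta_aic"].quantile(list(q))


def genomewide_delta_aic(matrix: ExpressionMatrix, tree: dendropy.Tree,
                         focal_species: str = "pig") -> DeltaAICResult:
    """dAIC for every gene of a log2 expression matrix.

    ``focal_species`` may be a tip label, or ``"best"`` to score each gene
    by its best single-species shift (max lnL1 over all tips, still k1=3).
    Genes whose fits are degenerate (variance floored) are excluded from
    the table and listed separately.
    """
    matrix = matrix.to_log2()
    ctx = BMContext.from_tree(tree)
    missing = [sp for sp in ctx.labels if sp not in matrix.species]
    if missing:
        raise ValidationError(f"matrix missing species {missing}")
    if focal_species != "best" and focal_species not in ctx.labels:
        raise ValidationError(f"focal species {focal_species!r} is not a tip")

    values = matrix.values[ctx.labels].to_numpy(dtype=float)
    focal_list = ctx.labels if focal_species == "best" else [focal_species]
    rows, degenerate = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateFitWarning)
        for g, gene_id in enumerate(matrix.gene_ids):
            x = values[g]
            fit0 = fit_bm(ctx, x, warn=False)
            fits1 = [fit_shift(ctx, x, sp, warn=False) for sp in focal_list]
            fit1 = max(fits1, key=lambda f: f.log_likelihood)
            if fit0.degenerate or fit1.degenerate:
                degenerate.append(gene_id)
                continue
            rec = delta_aic(fit0, fit1, gene_id=gene_id)
            rows.append(vars(rec))
    columns = ["gene_id", "lnl0", "lnl1", "aic0", "aic1", "delta_aic",
               "delta_hat", "se_delta", "focal_species"]
    table = pd.DataFrame(rows, columns=columns)
    return DeltaAICResult(table=table, degenerate_genes=degenerate,
                          focal_species=focal_species)


def delta_aic_histogram(deltas, bins: int = 50) -> pd.DataFrame:
    """Binned dAIC counts for export (bin_left, bin_right, count)."""
    counts, edges = np.histogram(np.asarray(deltas, dtype=float), bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


# ---------------------------------------------------------------------------
# spatial neighborhoods

def spatial_neighbors(annotation: GeneAnnotation, focal_gene: str,
                      window_bp: int | None = 1_000_000,
                      n_nearest: int | None = None) -> list[str]:
    """Genes on the focal gene's chromosome that are "spatially close".

    With ``window_bp``, returns genes whose (0-based, half-open) interval
    intersects the focal interval extended by the window on both sides.
    With ``n_nearest``, returns the n genes with the smallest midpoint
    distance (ties broken by gene id).  The focal gene itself is excluded;
    the result is sorted by genomic position for determinism.
    """
    focal = annotation.row(focal_gene)
    table = annotation.table
    same = table[(table["chrom"] == focal["chrom"]) & (table["gene_id"] != focal_gene)]
    if n_nearest is not None:
        if n_nearest < 0:
            raise ValidationError("n_nearest must be >= 0")
        mid = (same["start"] + same["end"]) / 2.0
        focal_mid = (focal["start"] + focal["end"]) / 2.0
        ranked = same.assign(_dist=(mid - focal_mid).abs()).sort_values(
            ["_dist", "gene_id"], kind="mergesort"
        )
        chosen = ranked.head(n_nearest)
    else:
        if window_bp is None or window_bp < 0:
            raise ValidationError("window_bp must be a non-negative integer")
        lo = focal["start"] - window_bp
        hi = focal["end"] + window_bp
        chosen = same[(same["start"] < hi) & (same["end"] > lo)]
    chosen = chosen.sort_values(["start", "gene_id"], kind="mergesort")
    return list(chosen["gene_id"])


# ---------------------------------------------------------------------------
# resampling null and Wilcoxon

@dataclass
class ResamplingNull:
    """Null distribution of median dAIC over random same-size gene draws."""

    medians: np.ndarray
    draw_size: int
    n_iter: int
    seed: int
    pool_size: int
    focal_gene: str | None = None


def resampled_median_null(pool_deltas, draw_size: int, n_iter: int = 10_000,
                          seed: int = 0, focal_gene: str | None = None) -> ResamplingNull:
    """Medians of ``n_iter`` without-replacement draws from a dAIC pool."""
    pool = np.asarray(pool_deltas, dtype=float)
    if draw_size < 1:
        raise ValidationError("draw_size must be >= 1")
    if pool.size < draw_size:
        raise ValidationError(
            f"pool of {pool.size} genes cannot supply draws of size {draw_size}"
        )
    rng = np.random.default_rng(seed)
    medians = np.empty(n_iter)
    for i in range(n_iter):
        medians[i] = np.median(rng.choice(pool, size=draw_size, replace=False))
    return ResamplingNull(medians=medians, draw_size=draw_size, n_iter=n_iter,
                          seed=seed, pool_size=int(pool.size), focal_gene=focal_gene)


@dataclass
class WilcoxonResult:
    u: float
    p_value: float
    method: str  # "exact" or "normal"


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> WilcoxonResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact p by enumeration when both samples have n <= 12 and there are no
    ties; otherwise a tie-corrected normal approximation with a sign-aware
    continuity correction (so identical samples give p = 1 exactly).
    Returns U for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")

    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and a.size <= 12 and b.size <= 12:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="exact")
        return WilcoxonResult(u=float(res.statistic), p_value=float(res.pvalue),
                              method="exact")

    n1, n2 = a.size, b.size
    ranks = stats.rankdata(combined)
    u1 = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    n = n1 + n2
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:  # every observation identical
        return WilcoxonResult(u=u1, p_value=1.0, method="normal")
    cc = 0.5 * np.sign(u1 - mean_u)  # toward the mean; zero at the center
    z = (u1 - mean_u - cc) / np.sqrt(var_u)
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    else:
        p = stats.norm.cdf(z)
    return WilcoxonResult(u=u1, p_value=float(min(p, 1.0)), method="normal")


# ---------------------------------------------------------------------------
# report

@dataclass
class ShiftReport:
    """Where the focal gene's dAIC sits relative to neighbors and the null."""

    focal_gene: str | None
    focal_delta_aic: float
    n_neighbors: int
    percentile_vs_null_medians: float
    percentile_vs_genomewide: float | None
    neighbor_vs_null_wilcoxon: WilcoxonResult | None
    focal_vs_null_less_p: float


def shift_report(focal_delta: float, neighbor_deltas, null: ResamplingNull,
                 genomewide_deltas=None) -> ShiftReport:
    """Summarize a focal gene against its neighborhood and the resampling null.

    Percentiles are ``100 * fraction of reference values strictly below the
    focal dAIC`` (0 when the focal value sits below everything).  The
    neighbor set is compared to the null medians by a two-sided Wilcoxon
    rank-sum test; with an empty neighbor set the report degrades to the
    focal-vs-null percentile only, with a warning.
    """
    neighbor_deltas = np.asarray(list(neighbor_deltas), dtype=float)
    pct_null = 100.0 * float(np.mean(null.medians < focal_delta))
    pct_gw = None
    if genomewide_deltas is not None:
        gw = np.asarray(list(genomewide_deltas), dtype=float)
        pct_gw = 100.0 * float(np.mean(gw < focal_delta))
    if neighbor_deltas.size == 0:
        warnings.warn("empty neighbor set: reporting focal-vs-null only", stacklevel=2)
        wilcoxon = None
    else:
        wilcoxon = wilcoxon_rank_sum(neighbor_deltas, null.medians,
                                     alternative="two-sided")
    focal_less = wilcoxon_rank_sum([focal_delta], null.medians, alternative="less")
    return ShiftReport(focal_gene=null.focal_gene, focal_delta_aic=float(focal_delta),
                       n_neighbors=int(neighbor_deltas.size),
                       percentile_vs_null_medians=pct_null,
                       percentile_vs_genomewide=pct_gw,
                       neighbor_vs_null_wilcoxon=wilcoxon,
                       focal_vs_null_less_p=float(focal_less.p_value))
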