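"""Expression trees from 1 - Spearman distances, and divergence statistics.

For one tissue, pairwise distances between species are ``1 - rho`` over the
shared single-copy gene set (``rho`` = Spearman's rank correlation, average
ranks on ties), a neighbor-joining tree is built from the distance matrix,
and the tree's total branch length (TBL) summarizes how much expression
divergence the tissue has accumulated.  Because the distance is rank-based,
any strictly monotone transform of the expression values (e.g. log2(x+1))
leaves the distance matrix bit-identical.

Neighbor joining is the classic Saitou-Nei agglomeration with the
Studier-Keppler O(n^3) Q-criterion; ties in the Q minimization are broken
by lexicographic taxon-pair order, and negative estimated edge lengths are
clamped to zero (the pre-clamp values are kept on the result).  Additive
input matrices are reproduced exactly, so clamping never triggers on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import ConstantVectorError, NegativeEdgeWarning, ValidationError


# ---------------------------------------------------------------------------
# distances

def spearman_distance(x, y) -> float:
    """1 - Spearman rank correlation of two equal-length vectors.

    Average ranks are assigned to ties.  The result lies in [0, 2]:
    0 for identical rank order, 2 for exactly reversed order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("vectors must be 1-D and of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(1.0 - rho)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise 1 - rho distances between taxa."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate taxon labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def distance_matrix(matrix: ExpressionMatrix) -> DistanceMatrix:
    """All pairwise 1 - Spearman distances between species columns."""
    species = matrix.species
    if len(species) < 3:
        raise ValidationError("need at least 3 species")
    arr = matrix.values.to_numpy(dtype=float)
    for j, sp in enumerate(species):
        if np.ptp(arr[:, j]) == 0:
            raise ConstantVectorError(f"species column {sp!r} is constant")
    rho = stats.spearmanr(arr, axis=0).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return DistanceMatrix(tuple(species), d)


# ---------------------------------------------------------------------------
# neighbor joining

@dataclass
class ExpressionTree:
    """Unrooted NJ tree with estimated branch lengths for one tissue."""

    tree: dendropy.Tree
    tissue: str | None = None
    n_clamped: int = 0
    clamped_values: list[float] = field(default_factory=list)

    @property
    def total_branch_length(self) -> float:
        return total_branch_length(self.tree)


def _pair_key(rep_a: str, rep_b: str) -> tuple[str, str]:
    return (rep_a, rep_b) if rep_a <= rep_b else (rep_b, rep_a)


def neighbor_joining(dm: DistanceMatrix, tissue: str | None = None) -> ExpressionTree:
    """Saitou-Nei neighbor joining on a distance matrix.

    Agglomerates with the Studier-Keppler Q-criterion
    ``Q(i,j) = (r-2) d(i,j) - R_i - R_j`` until three clusters remain, then
    closes with the exact three-taxon formula.  Tie-breaks in the Q
    minimization use lexicographic order of the clusters' smallest leaf
    labels; negative edge-length estimates are clamped to 0 (counted and
    recorded, with a :class:`NegativeEdgeWarning`).
    """
    if dm.n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")

    taxa = dendropy.TaxonNamespace(list(dm.labels))
    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # lexicographically smallest leaf label per cluster
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)
        reps.append(label)
    d = dm.values.copy()

    clamped: list[float] = []

    def settle(length: float) -> float:
        if length < 0:
            clamped.append(float(length))
            return 0.0
        return float(length)

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - row_sums[i] - row_sums[j]
                key = _pair_key(reps[i], reps[j])
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and best is not None and key < best[2]
                ):
                    best_q = q
                    best = (i, j, key)
        i, j, _ = best
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        child_i, child_j = nodes[i], nodes[j]
        parent.add_child(child_i)
        parent.add_child(child_j)
        child_i.edge.length = settle(li)
        child_j.edge.length = settle(lj)

        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # exact closure for the final three clusters
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    center = dendropy.Node()
    for node, length in zip(nodes, (la, lb, lc)):
        center.add_child(node)
        node.edge.length = settle(length)

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    if clamped:
        warnings.warn(
            f"clamped {len(clamped)} negative NJ edge length(s) to 0 "
            f"(pre-clamp min {min(clamped):.3g})",
            NegativeEdgeWarning,
            stacklevel=2,
        )
    return ExpressionTree(tree, tissue=tissue, n_clamped=len(clamped),
                          clamped_values=clamped)


def total_branch_length(tree: dendropy.Tree | ExpressionTree) -> float:
    """Sum of all edge lengths; raises if any non-root edge lacks a length."""
    if isinstance(tree, ExpressionTree):
        tree = tree.tree
    total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge carries no length
        if edge.length is None:
            raise ValidationError("tree has an edge without a branch length")
        total += edge.length
    return float(total)


# ---------------------------------------------------------------------------
# tissue report

def average_replicates(values: pd.DataFrame, species_of: dict[str, str]) -> pd.DataFrame:
    """Average replicate columns into one column per species.

    ``species_of`` maps each input column to its species label.  This is
    the configurable pre-averaging step for matrices with within-species
    replicates; the default pipeline carries one column per species.
    """
    missing = set(values.columns) - set(species_of)
    if missing:
        raise ValidationError(f"no species mapping for columns {sorted(missing)}")
    return values.T.groupby(values.columns.map(species_of.get)).mean().T


def tissue_divergence_report(matrices: dict[str, ExpressionMatrix]) -> pd.DataFrame:
    """Build one NJ tree per tissue and tabulate total branch lengths.

    Returns a DataFrame with one row per tissue (tissue, n_taxa,
    total_branch_length, n_clamped_edges, rank), ordered by ascending TBL
    (rank 1 = least diverged tissue).  Tissues whose taxon sets differ from
    the others are flagged in a ``shared_taxa`` column with a warning.
    """
    if not matrices:
        raise ValidationError("need at least one tissue")
    taxon_sets = {t: frozenset(m.species) for t, m in matrices.items()}
    common = frozenset.intersection(*taxon_sets.values())
    rows = []
    for tissue in sorted(matrices):
        result = neighbor_joining(distance_matrix(matrices[tissue]), tissue=tissue)
        rows.append(
            {
                "tissue": tissue,
                "n_taxa": len(taxon_sets[tissue]),
                "total_branch_length": result.total_branch_length,
                "n_clamped_edges": result.n_clamped,
                "shared_taxa": taxon_sets[tissue] == common,
            }
        )
    mismatched = [r["tissue"] for r in rows if not r["shared_taxa"]]
    if mismatched:
        warnings.warn(f"tissues with mismatched taxon sets: {mismatched}", stacklevel=2)
    report = pd.DataFrame(rows).sort_values(
        ["total_branch_length", "tissue"], kind="mergesort", ignore_index=True
    )
    report["rank"] = np.arange(1, len(report) + 1)
    return report
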