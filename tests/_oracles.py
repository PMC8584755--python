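"""Independent brute-force oracles used by the tests.

Everything here recomputes quantities by enumeration, path-walking or grid
search, deliberately avoiding the package's own closed-form / agglomerative
code paths.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np


# ---------------------------------------------------------------------------
# random additive trees and path distances

def random_binary_tree(rng: np.random.Generator, n_taxa: int,
                       length_range=(0.1, 1.0)) -> dendropy.Tree:
    """Random rooted binary tree by sequential joins, random edge lengths."""
    taxa = dendropy.TaxonNamespace([f"t{i:02d}" for i in range(n_taxa)])
    nodes = []
    for taxon in taxa:
        node = dendropy.Node()
        node.taxon = taxon
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(*length_range))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def _root_paths(tree: dendropy.Tree) -> dict[str, list]:
    """Map each leaf label to its list of nodes from the root down."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        chain = [leaf]
        node = leaf
        while node.parent_node is not None:
            node = node.parent_node
            chain.append(node)
        paths[leaf.taxon.label] = list(reversed(chain))
    return paths


def pathwalk_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix by explicit root-path walking."""
    paths = _root_paths(tree)
    labels = sorted(paths)
    n = len(labels)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pa, pb = paths[labels[i]], paths[labels[j]]
        shared = 0
        while shared < min(len(pa), len(pb)) and pa[shared] is pb[shared]:
            shared += 1
        dist = sum(node.edge.length or 0.0 for node in pa[shared:])
        dist += sum(node.edge.length or 0.0 for node in pb[shared:])
        D[i, j] = D[j, i] = dist
    return labels, D


def pathwalk_bm_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """BM tip covariance via explicit MRCA-depth walking (rooted tree)."""
    paths = _root_paths(tree)
    labels = sorted(paths)
    n = len(labels)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            pa, pb = paths[labels[i]], paths[labels[j]]
            shared = 0
            while shared < min(len(pa), len(pb)) and pa[shared] is pb[shared]:
                shared += 1
            depth = sum(node.edge.length or 0.0 for node in pa[1:shared])
            C[i, j] = C[j, i] = depth
    return labels, C


# ---------------------------------------------------------------------------
# grid-search likelihood oracle

def _lnl_quadratic_terms(C: np.ndarray, x: np.ndarray, e: np.ndarray | None):
    """Inner products under C^-1 needed to evaluate the Gaussian lnL."""
    n = len(x)
    one = np.ones(n)
    cols = [x, one] + ([e] if e is not None else [])
    sol = np.linalg.solve(C, np.stack(cols, axis=1))
    ip = np.stack(cols, axis=1).T @ sol  # gram matrix under C^-1
    sign, logdet = np.linalg.slogdet(C)
    assert sign > 0
    return ip, logdet


def grid_max_lnl(C: np.ndarray, x: np.ndarray, focal_index: int | None = None,
                 pts: int = 31, stages: int = 18) -> float:
    """Maximum Gaussian log-likelihood by zooming grid search.

    Model: x ~ N(mu * 1 + delta * e_focal, sigma2 * C); delta dimension
    dropped when ``focal_index`` is None.  Evaluates the likelihood
    directly on a shrinking grid over (mu[, delta], log sigma2).
    """
    n = len(x)
    e = None
    if focal_index is not None:
        e = np.zeros(n)
        e[focal_index] = 1.0
    ip, logdet = _lnl_quadratic_terms(C, x, e)

    span = float(np.ptp(x)) + 1.0
    var = float(np.var(x)) + 1e-8
    mu_rng = [float(x.min()) - span, float(x.max()) + span]
    de_rng = [-2.0 * span, 2.0 * span]
    ls_rng = [np.log(var * 1e-5), np.log(var * 1e4)]

    def quad(mu, de):
        # (x - mu 1 - de e)' C^-1 (x - mu 1 - de e) from the gram matrix
        q = (
            ip[0, 0]
            - 2.0 * mu * ip[0, 1]
            + mu**2 * ip[1, 1]
        )
        if e is not None:
            q = q - 2.0 * de * ip[0, 2] + 2.0 * mu * de * ip[1, 2] + de**2 * ip[2, 2]
        return q

    best = -np.inf
    for _ in range(stages):
        mu_g = np.linspace(*mu_rng, pts)
        ls_g = np.linspace(*ls_rng, pts)
        de_g = np.linspace(*de_rng, pts) if e is not None else np.array([0.0])
        q = quad(mu_g[:, None], de_g[None, :])  # (mu, de)
        s2 = np.exp(ls_g)
        lnl = -0.5 * (
            n * (np.log(2 * np.pi) + ls_g[None, None, :])
            + logdet
            + q[:, :, None] / s2[None, None, :]
        )
        flat = int(np.argmax(lnl))
        i, j, k = np.unravel_index(flat, lnl.shape)
        best = max(best, float(lnl[i, j, k]))

        def shrink(grid, idx, rng_pair):
            lo = grid[max(idx - 1, 0)]
            hi = grid[min(idx + 1, len(grid) - 1)]
            width = grid[-1] - grid[0]
            if idx == 0:
                lo -= width
            if idx == len(grid) - 1:
                hi += width
            rng_pair[0], rng_pair[1] = float(lo), float(hi)

        shrink(mu_g, i, mu_rng)
        if e is not None:
            shrink(de_g, j, de_rng)
        shrink(ls_g, k, ls_rng)
    return best


# ---------------------------------------------------------------------------
# exact rank-sum enumeration

def mann_whitney_exact_two_sided(a, b) -> float:
    """Two-sided exact rank-sum p-value by full enumeration (no ties)."""
    a = list(map(float, a))
    b = list(map(float, b))
    combined = sorted(a + b)
    assert len(set(combined)) == len(combined), "oracle requires no ties"
    ranks = {v: r + 1 for r, v in enumerate(combined)}
    n1 = len(a)

    def u_of(sample_ranks):
        return sum(sample_ranks) - n1 * (n1 + 1) / 2

    observed = u_of([ranks[v] for v in a])
    mean_u = n1 * len(b) / 2.0
    obs_dev = abs(observed - mean_u)
    total = 0
    extreme = 0
    all_ranks = list(ranks.values())
    for combo in itertools.combinations(all_ranks, n1):
        total += 1
        if abs(u_of(combo) - mean_u) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total


def median_draw_distribution(pool, draw_size) -> dict[float, float]:
    """Exact distribution of the median over all without-replacement draws."""
    pool = list(map(float, pool))
    outcomes: dict[float, int] = {}
    total = 0
    for combo in itertools.combinations(pool, draw_size):
        total += 1
        med = float(np.median(combo))
        outcomes[med] = outcomes.get(med, 0) + 1
    return {k: v / total for k, v in outcomes.items()}
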