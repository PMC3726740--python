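"""Significance tests and supporting statistics.

The leaf-label permutation test asks whether a tree fits a geographic
gradient better than expected by chance: leaf-to-site assignments are
shuffled uniformly (tree shape fixed), the optimal layout is recomputed
for each shuffle, and the p-value is the proportion of permutations with
no more crossings than observed. Also here: the Mantel test, ordinary
least-squares regression, Bray-Curtis dissimilarity, and UPGMA
clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps

from geoaxes.geodata import (
    CountTable,
    DissimilarityMatrix,
    GeodataError,
    GeoTree,
    LocationSet,
    TreeNode,
)
from geoaxes.layout import CompiledTree, minimum_crossings
from geoaxes.sweep import SiteOrdering, project_and_order

__all__ = [
    "PermutationTestResult",
    "MantelResult",
    "RegressionResult",
    "permutation_test",
    "null_crossing_distribution",
    "null_critical_value",
    "mantel",
    "linear_regression",
    "bray_curtis",
    "upgma",
    "cophenetic_distances",
]

DEFAULT_SEED = 42


@dataclass(frozen=True)
class PermutationTestResult:
    observed_crossings: int
    null_crossings: tuple[int, ...]
    p_value: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int
    alternative: str = "greater"


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# Permutation test for tree-gradient fit
# ---------------------------------------------------------------------------

def _null_distribution(compiled: CompiledTree, positions: list[int],
                       n_permutations: int, rng: np.random.Generator
                       ) -> list[int]:
    base = np.asarray(positions, dtype=np.int64)
    out = []
    for _ in range(n_permutations):
        perm = rng.permutation(base)
        out.append(minimum_crossings(compiled, perm.tolist()))
    return out


def permutation_test(
    tree: GeoTree,
    ordering: SiteOrdering,
    n_permutations: int = 1000,
    seed: int = DEFAULT_SEED,
    conservative: bool = False,
) -> PermutationTestResult:
    """Leaf-label permutation test of tree-versus-gradient fit.

    Each permutation uniformly shuffles the leaf-to-site assignment while
    keeping the tree shape fixed, and the minimum crossing number is
    recomputed. The p-value is the proportion of permutations with
    crossings less than or equal to the observed value (ties counted in
    the numerator), so p = 0 is attainable. With ``conservative=True``
    the (b + 1) / (m + 1) variant is used instead, equivalent to counting
    the unpermuted tree as one more draw from the null.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    compiled = CompiledTree(tree)
    positions = compiled.positions_for(ordering)
    observed = minimum_crossings(compiled, positions)
    rng = np.random.default_rng(seed)
    null = _null_distribution(compiled, positions, n_permutations, rng)
    b = sum(1 for v in null if v <= observed)
    if conservative:
        p = (b + 1) / (n_permutations + 1)
    else:
        p = b / n_permutations
    return PermutationTestResult(
        observed_crossings=observed,
        null_crossings=tuple(null),
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


def null_crossing_distribution(
    tree: GeoTree,
    locs: LocationSet,
    n_permutations: int = 1000,
    seed: int = DEFAULT_SEED,
    angle: float = 90.0,
) -> list[int]:
    """Null distribution of optimal crossings under uniform relabeling.

    Computed against the site ordering at one reference ``angle``
    (default 90 deg, the longitudinal axis). When all sites are distinct
    the null is invariant to this choice — any fixed ordering of distinct
    sites is a relabeling of any other — so a single distribution serves
    every axis of a sweep. Co-located sites (tie groups) can break the
    invariance; a warning is emitted in that case.
    """
    ordering = project_and_order(locs, angle)
    if any(len(g) > 1 for g in ordering.tie_groups):
        warnings.warn(
            "co-located sites form tie groups; the permutation null may "
            "differ between axis angles",
            stacklevel=2,
        )
    compiled = CompiledTree(tree)
    positions = compiled.positions_for(ordering)
    rng = np.random.default_rng(seed)
    return _null_distribution(compiled, positions, n_permutations, rng)


def null_critical_value(
    tree: GeoTree,
    locs: LocationSet,
    alpha: float,
    n_permutations: int = 1000,
    seed: int = DEFAULT_SEED,
    angle: float = 90.0,
) -> int:
    """Largest crossing count c with (# null < c) / m <= alpha.

    The value below which an observed crossing number would be declared
    significant at level ``alpha`` (drawn as the horizontal critical line
    on a sweep profile). Computed from a single permutation null at the
    reference ``angle``; see :func:`null_crossing_distribution`.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    null = sorted(
        null_crossing_distribution(tree, locs, n_permutations, seed, angle)
    )
    m = len(null)
    k = min(int(alpha * m), m - 1)
    return null[k]


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(
    A: DissimilarityMatrix,
    B: DissimilarityMatrix,
    n_permutations: int = 999,
    seed: int = DEFAULT_SEED,
    alternative: str = "greater",
    conservative: bool = False,
) -> MantelResult:
    """Mantel test of correlation between two dissimilarity matrices.

    r is the Pearson correlation over corresponding upper-triangle
    entries; significance comes from simultaneous row/column permutations
    of B. One-sided ("greater") by default; ``alternative="two-sided"``
    compares absolute correlations. The p-value is the plain proportion
    of permuted correlations at least as extreme as the observed one
    (ties counted), so p = 0 is attainable; ``conservative=True`` applies
    the (b + 1) / (m + 1) correction.
    """
    if A.ids != B.ids:
        raise GeodataError("Mantel test requires identical ids in "
                           "identical order")
    n = len(A)
    if n < 3:
        raise GeodataError("Mantel test requires at least 3 objects")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    a = A.condensed()
    b = B.condensed()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise GeodataError("matrix is constant off-diagonal; correlation "
                           "undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    Bv = B.values
    count = 0
    for _ in range(n_permutations):
        idx = rng.permutation(n)
        b_perm = Bv[np.ix_(idx, idx)][iu]
        r_perm = float(np.corrcoef(a, b_perm)[0, 1])
        if alternative == "greater":
            extreme = r_perm >= r_obs - 1e-12
        else:
            extreme = abs(r_perm) >= abs(r_obs) - 1e-12
        count += extreme
    if conservative:
        p = (count + 1) / (n_permutations + 1)
    else:
        p = count / n_permutations
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_permutations,
                        seed=seed, alternative=alternative)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def linear_regression(x: Sequence[float], y: Sequence[float]
                      ) -> RegressionResult:
    """Ordinary least squares of y on x.

    Two-sided p-value for slope != 0 from the t statistic with n - 2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("regression requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Bray-Curtis and UPGMA
# ---------------------------------------------------------------------------

def bray_curtis(table: CountTable) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity between the rows of a count
    table: BC(u, v) = 1 - 2 * sum_k min(u_k, v_k) / (sum u + sum v)."""
    values = table.values
    if values.shape[0] < 2:
        raise GeodataError("need at least 2 samples")
    if np.any(values.sum(axis=1) == 0):
        zero = [sid for sid, tot in
                zip(table.sample_ids, values.sum(axis=1)) if tot == 0]
        raise GeodataError(f"all-zero sample row(s): {', '.join(zero)}")
    d = squareform(pdist(values, metric="braycurtis"))
    return DissimilarityMatrix(table.sample_ids, d)


def upgma(D: DissimilarityMatrix) -> GeoTree:
    """UPGMA (average-linkage) clustering of a dissimilarity matrix.

    Returns an ultrametric tree: each merge creates a node at height
    equal to half the between-cluster average distance, and branch
    lengths are height differences, so the path distance between two
    leaves equals the average distance at which their clusters merged.
    Ties in the merge distance are broken by the lexicographically
    smallest pair of cluster labels (a cluster is labelled by its
    smallest member).
    """
    n = len(D)
    if n < 2:
        raise GeodataError("UPGMA requires at least 2 objects")
    # active clusters: label -> (node, size, height); label = min member id
    nodes: dict[str, tuple[TreeNode, int, float]] = {
        sid: (TreeNode(label=sid), 1, 0.0) for sid in D.ids
    }
    dist: dict[frozenset[str], float] = {}
    ids = D.ids
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((ids[i], ids[j]))] = float(D.values[i, j])

    while len(nodes) > 1:
        best_pair: tuple[str, str] | None = None
        best_d = np.inf
        for key, dval in dist.items():
            a, b = sorted(key)
            if (dval < best_d - 1e-15
                    or (abs(dval - best_d) <= 1e-15
                        and (best_pair is None or (a, b) < best_pair))):
                best_d = dval
                best_pair = (a, b)
        assert best_pair is not None
        a, b = best_pair
        node_a, size_a, _ = nodes[a]
        node_b, size_b, _ = nodes[b]
        height = best_d / 2.0
        merged = TreeNode(children=[node_a, node_b])
        # branch lengths make leaf depths equal to the node height
        for child, child_label in ((node_a, a), (node_b, b)):
            child.length = height - nodes[child_label][2]
        new_label = min(a, b)
        # average-linkage update, weighted by cluster sizes
        for other in list(nodes):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new_label, other))] = (
                (size_a * da + size_b * db) / (size_a + size_b)
            )
        dist.pop(frozenset((a, b)))
        del nodes[a], nodes[b]
        nodes[new_label] = (merged, size_a + size_b, height)

    root = next(iter(nodes.values()))[0]
    return GeoTree(root)


def cophenetic_distances(tree: GeoTree) -> DissimilarityMatrix:
    """Leaf-to-leaf path distances induced by a tree's branch lengths."""
    labels = tree.leaf_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))

    def rec(node: TreeNode) -> list[tuple[int, float]]:
        if node.is_leaf:
            return [(index[node.label], 0.0)]
        gathered: list[list[tuple[int, float]]] = []
        for child in node.children:
            sub = [(i, d + (child.length or 0.0)) for i, d in rec(child)]
            gathered.append(sub)
        for gi in range(len(gathered)):
            for gj in range(gi + 1, len(gathered)):
                for i, di in gathered[gi]:
                    for j, dj in gathered[gj]:
                        out[i, j] = out[j, i] = di + dj
        return [pair for sub in gathered for pair in sub]

    rec(tree.root)
    return DissimilarityMatrix(labels, out)
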