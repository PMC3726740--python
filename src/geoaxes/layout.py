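"""Minimum-crossing tree layout against a fixed site ordering.

Drawing tree leaves on one line and ordered sample sites on a parallel
line, each leaf connects to its site; the crossing number counts
intersecting connector pairs. For a fixed left-to-right leaf order this
equals the number of strict inversions between the leaf sequence of site
positions and the site order (leaves sharing a site never cross each
other). The tree topology constrains attainable leaf orders: children of
every internal node may be permuted independently. Crossings decompose
over internal nodes, so the global optimum is found by solving a linear
ordering problem per node — exactly, by subset dynamic programming for
small degree and branch-and-bound otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from geoaxes.geodata import GeoTree, TreeNode

__all__ = [
    "LayoutResult",
    "count_crossings",
    "count_crossings_quadratic",
    "child_cost_matrix",
    "solve_child_order",
    "optimal_layout",
    "brute_force_layout",
    "minimum_crossings",
    "compile_tree",
    "CompiledTree",
    "LayoutError",
]


class LayoutError(ValueError):
    pass


class SiteOrderingLike(Protocol):
    """Anything mapping site ids to integer positions with ties allowed."""

    position: dict[str, int]
    n_positions: int


@dataclass(frozen=True)
class LayoutResult:
    """Outcome of crossing minimization for one tree/ordering pair.

    ``per_node_child_orders`` maps the preorder index of each internal
    node to the chosen permutation of its children (0-based, relative to
    the input child order).
    """

    crossings: int
    leaf_order: tuple[str, ...]
    per_node_child_orders: dict[int, tuple[int, ...]]


# ---------------------------------------------------------------------------
# Inversion counting
# ---------------------------------------------------------------------------

def count_crossings(leaf_sites: Sequence[int], n_sites: int) -> int:
    """Count crossings for a fixed layout.

    ``leaf_sites`` gives, for each leaf in left-to-right layout order, the
    position of its site in the site ordering. The crossing number is the
    number of leaf pairs (a before b) with ``pos(a) > pos(b)``; pairs on
    the same site contribute nothing. O(n log m) via a Fenwick tree over
    the ``n_sites`` positions.
    """
    m = int(n_sites)
    fen = [0] * (m + 1)
    inversions = 0
    seen = 0
    for p in leaf_sites:
        p = int(p)
        if p < 0 or p >= m:
            raise LayoutError(f"site position {p} out of range [0, {m})")
        # count of already-placed leaves with position <= p
        i = p + 1
        le = 0
        while i > 0:
            le += fen[i]
            i -= i & -i
        inversions += seen - le
        i = p + 1
        while i <= m:
            fen[i] += 1
            i += i & -i
        seen += 1
    return inversions


def count_crossings_quadratic(leaf_sites: Sequence[int]) -> int:
    """Reference O(n^2) pairwise count (testing oracle)."""
    n = len(leaf_sites)
    return sum(
        1
        for a in range(n)
        for b in range(a + 1, n)
        if leaf_sites[a] > leaf_sites[b]
    )


# ---------------------------------------------------------------------------
# Per-node linear ordering problem
# ---------------------------------------------------------------------------

def _pair_cost(pi: Sequence[int], pj: Sequence[int]) -> int:
    """#(p in pi, q in pj) with p > q, for sorted position lists."""
    total = 0
    j = 0
    nj = len(pj)
    for p in pi:
        while j < nj and pj[j] < p:
            j += 1
        total += j
    return total


def _cost_matrix(child_positions: list[list[int]]) -> list[list[int]]:
    d = len(child_positions)
    costs = [[0] * d for _ in range(d)]
    for i in range(d):
        for j in range(i + 1, d):
            costs[i][j] = _pair_cost(child_positions[i], child_positions[j])
            costs[j][i] = _pair_cost(child_positions[j], child_positions[i])
    return costs


def child_cost_matrix(node: TreeNode, site_order: SiteOrderingLike) -> np.ndarray:
    """d x d matrix of between-subtree crossing costs at one internal node.

    Entry (i, j) is the number of leaf pairs (a in subtree i, b in subtree
    j) with ``pos(site(a)) > pos(site(b))`` — the crossings incurred when
    child i is laid out entirely before child j. Independent of the
    within-subtree orders.
    """
    if len(node.children) < 2:
        raise LayoutError("child_cost_matrix requires an internal node "
                          "with >= 2 children")
    pos = site_order.position
    child_positions = []
    for child in node.children:
        ps = sorted(pos[leaf.site_id] for leaf in _iter_leaves(child))
        child_positions.append(ps)
    return np.array(_cost_matrix(child_positions), dtype=np.int64)


def _iter_leaves(node: TreeNode):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(reversed(n.children))


def solve_child_order(costs) -> tuple[list[int], int]:
    """Exact solution of the per-node linear ordering problem.

    Finds a permutation pi of the d children minimizing
    ``sum_{i before j under pi} costs[i][j]``; among ties the
    lexicographically smallest permutation is returned. Subset dynamic
    programming for d <= 15, depth-first branch-and-bound (lower bound:
    sum of pairwise minima over unplaced pairs) beyond.
    """
    costs = [list(map(int, row)) for row in np.asarray(costs)]
    d = len(costs)
    if d == 0:
        return [], 0
    if d == 1:
        return [0], 0
    if d == 2:
        if costs[0][1] <= costs[1][0]:
            return [0, 1], costs[0][1]
        return [1, 0], costs[1][0]
    if d <= 15:
        return _solve_subset_dp(costs, d)
    return _solve_branch_and_bound(costs, d)


def _solve_subset_dp(costs: list[list[int]], d: int) -> tuple[list[int], int]:
    full = (1 << d) - 1
    # g[k][S] = cost of appending k after placed-set S
    g = [[0] * (full + 1) for _ in range(d)]
    for k in range(d):
        gk = g[k]
        for s in range(1, full + 1):
            low = s & -s
            gk[s] = gk[s ^ low] + costs[low.bit_length() - 1][k]
    # b[S] = minimum remaining cost given the set S already placed
    b = [0] * (full + 1)
    for s in range(full - 1, -1, -1):
        best = None
        for k in range(d):
            bit = 1 << k
            if s & bit:
                continue
            v = g[k][s] + b[s | bit]
            if best is None or v < best:
                best = v
        b[s] = best  # type: ignore[assignment]
    # forward reconstruction -> lexicographically smallest optimum
    perm: list[int] = []
    s = 0
    while s != full:
        for k in range(d):
            bit = 1 << k
            if s & bit:
                continue
            if g[k][s] + b[s | bit] == b[s]:
                perm.append(k)
                s |= bit
                break
    return perm, b[0]


def _perm_cost(costs: list[list[int]], perm: list[int]) -> int:
    return sum(costs[perm[i]][perm[j]]
               for i in range(len(perm)) for j in range(i + 1, len(perm)))


def _insertion_local_search(costs: list[list[int]],
                            perm: list[int]) -> list[int]:
    """First-improvement insertion moves until a local optimum."""
    d = len(perm)
    perm = list(perm)
    improved = True
    while improved:
        improved = False
        for a in range(d):
            k = perm[a]
            rest = perm[:a] + perm[a + 1:]
            base = _perm_cost(costs, perm)
            for b in range(d):
                if b == a:
                    continue
                cand = rest[:b] + [k] + rest[b:]
                if _perm_cost(costs, cand) < base:
                    perm = cand
                    improved = True
                    break
            if improved:
                break
    return perm


def _solve_branch_and_bound(costs: list[list[int]], d: int) -> tuple[list[int], int]:
    pairmin = [[min(costs[i][j], costs[j][i]) for j in range(d)]
               for i in range(d)]
    lb_full = sum(pairmin[i][j] for i in range(d) for j in range(i + 1, d))
    # greedy incumbent (net-outflow heuristic + insertion local search)
    # tightens pruning from the start; it only seeds the bound — the DFS
    # below still visits the lexicographically smallest optimum first
    # and records it
    greedy = sorted(range(d),
                    key=lambda i: sum(costs[i][j] - costs[j][i]
                                      for j in range(d)))
    greedy = _insertion_local_search(costs, greedy)
    best_cost = _perm_cost(costs, greedy)
    best_perm: list[int] | None = None
    placed = [False] * d
    prefix: list[int] = []

    def rec(cost_so_far: int, lb_rest: int) -> None:
        nonlocal best_cost, best_perm
        if len(prefix) == d:
            if cost_so_far < best_cost or (best_perm is None
                                           and cost_so_far <= best_cost):
                best_cost = cost_so_far
                best_perm = prefix.copy()
            return
        for k in range(d):
            if placed[k]:
                continue
            add = sum(costs[i][k] for i in prefix)
            sub = sum(pairmin[k][j] for j in range(d)
                      if not placed[j] and j != k)
            new_cost = cost_so_far + add
            new_lb = lb_rest - sub
            if new_cost + new_lb > best_cost:
                continue
            placed[k] = True
            prefix.append(k)
            rec(new_cost, new_lb)
            prefix.pop()
            placed[k] = False

    rec(0, lb_full)
    if best_perm is None:  # greedy was optimal and lex-minimal
        best_perm = greedy
    return best_perm, best_cost


# ---------------------------------------------------------------------------
# Whole-tree optimal layout
# ---------------------------------------------------------------------------

class CompiledTree:
    """Topology of a georeferenced tree flattened for repeated layout runs.

    Postorder list of nodes; leaves reference a slot in the original
    left-to-right leaf sequence, so a layout evaluation only needs the
    vector of per-leaf site positions.
    """

    def __init__(self, tree: GeoTree):
        if not tree.georeferenced:
            raise LayoutError("tree must be georeferenced")
        self.leaf_labels = tuple(tree.leaf_labels)
        self.leaf_site_ids = tuple(tree.leaf_site_ids())
        self.nodes: list[tuple[bool, object, int]] = []
        # (is_leaf, payload, preorder_index); payload = leaf slot or
        # list of postorder child ids
        post_of: dict[int, int] = {}
        slot = 0
        stack: list[tuple[TreeNode, bool]] = [(tree.root, False)]
        while stack:
            node, expanded = stack.pop()
            if node.is_leaf:
                post_of[id(node)] = len(self.nodes)
                self.nodes.append((True, slot, node.index))
                slot += 1
                continue
            if expanded:
                child_ids = [post_of[id(c)] for c in node.children]
                post_of[id(node)] = len(self.nodes)
                self.nodes.append((False, child_ids, node.index))
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))
        self.n_leaves = slot

    def positions_for(self, site_order: SiteOrderingLike) -> list[int]:
        pos = site_order.position
        try:
            return [pos[s] for s in self.leaf_site_ids]
        except KeyError as exc:
            raise LayoutError(
                f"leaf site {exc.args[0]!r} missing from the site ordering"
            ) from exc


def compile_tree(tree: GeoTree) -> CompiledTree:
    return CompiledTree(tree)


def minimum_crossings(compiled: CompiledTree,
                      leaf_positions: Sequence[int]) -> int:
    """Minimum crossing number for one assignment of leaf site positions.

    Fast path used by the plane sweep and the permutation test: avoids
    building the full :class:`LayoutResult`.
    """
    vals: list[list[int] | None] = [None] * len(compiled.nodes)
    total = 0
    for idx, (is_leaf, payload, _) in enumerate(compiled.nodes):
        if is_leaf:
            vals[idx] = [int(leaf_positions[payload])]
        else:
            childs = [vals[c] for c in payload]  # type: ignore[index]
            costs = _cost_matrix(childs)  # type: ignore[arg-type]
            _, cost = solve_child_order(costs)
            total += cost
            merged = sorted(itertools.chain.from_iterable(childs))
            vals[idx] = merged
            for c in payload:  # type: ignore[union-attr]
                vals[c] = None  # free memory early
    return total


def optimal_layout(tree: GeoTree, site_order: SiteOrderingLike) -> LayoutResult:
    """Globally optimal (minimum-crossing) layout of ``tree``.

    Children of every internal node are permuted independently; the
    reported crossing number is the global minimum over all such layouts
    and equals the sum of per-node linear-ordering costs.
    """
    compiled = CompiledTree(tree)
    positions = compiled.positions_for(site_order)
    vals: list[list[int] | None] = [None] * len(compiled.nodes)
    orders: dict[int, tuple[int, ...]] = {}
    perm_of: list[list[int] | None] = [None] * len(compiled.nodes)
    total = 0
    for idx, (is_leaf, payload, pre_idx) in enumerate(compiled.nodes):
        if is_leaf:
            vals[idx] = [positions[payload]]
        else:
            childs = [vals[c] for c in payload]  # type: ignore[index]
            costs = _cost_matrix(childs)  # type: ignore[arg-type]
            perm, cost = solve_child_order(costs)
            total += cost
            orders[pre_idx] = tuple(perm)
            perm_of[idx] = perm
            vals[idx] = sorted(itertools.chain.from_iterable(childs))

    leaf_order = tuple(compiled.leaf_labels[s]
                       for s in _leaf_sequence(compiled, perm_of))
    return LayoutResult(crossings=total, leaf_order=leaf_order,
                        per_node_child_orders=orders)


def _leaf_sequence(compiled: CompiledTree,
                   perm_of: list[list[int] | None]) -> list[int]:
    """Leaf slots left-to-right after applying chosen child permutations."""
    root = len(compiled.nodes) - 1
    out: list[int] = []
    stack = [root]
    while stack:
        idx = stack.pop()
        is_leaf, payload, _ = compiled.nodes[idx]
        if is_leaf:
            out.append(payload)  # type: ignore[arg-type]
        else:
            perm = perm_of[idx]
            assert perm is not None
            for k in reversed(perm):
                stack.append(payload[k])  # type: ignore[index]
    return out


def brute_force_layout(tree: GeoTree, site_order: SiteOrderingLike,
                       max_layouts: int = 10 ** 6) -> LayoutResult:
    """Exhaustive-enumeration oracle with the same contract as
    :func:`optimal_layout`.

    Enumerates every combination of child permutations at every internal
    node and counts crossings directly; refuses instances with more than
    ``max_layouts`` consistent layouts.
    """
    compiled = CompiledTree(tree)
    positions = compiled.positions_for(site_order)
    internal = [i for i, (is_leaf, _, _) in enumerate(compiled.nodes)
                if not is_leaf]
    n_layouts = 1
    for i in internal:
        d = len(compiled.nodes[i][1])  # type: ignore[arg-type]
        for f in range(2, d + 1):
            n_layouts *= f
        if n_layouts > max_layouts:
            raise LayoutError(
                f"instance too large for brute force (> {max_layouts} "
                "layouts)"
            )
    n_pos = max(positions) + 1 if positions else 1

    best: tuple[int, dict[int, tuple[int, ...]], tuple[int, ...]] | None = None
    perm_choices = [
        list(itertools.permutations(range(len(compiled.nodes[i][1]))))
        for i in internal
    ]
    for combo in itertools.product(*perm_choices):
        perm_of: list[list[int] | None] = [None] * len(compiled.nodes)
        for i, perm in zip(internal, combo):
            perm_of[i] = list(perm)
        seq = _leaf_sequence(compiled, perm_of)
        crossings = count_crossings([positions[s] for s in seq], n_pos)
        if best is None or crossings < best[0]:
            orders = {compiled.nodes[i][2]: tuple(p)
                      for i, p in zip(internal, combo)}
            best = (crossings, orders, tuple(seq))
    assert best is not None
    crossings, orders, seq = best
    return LayoutResult(
        crossings=crossings,
        leaf_order=tuple(compiled.leaf_labels[s] for s in seq),
        per_node_child_orders=orders,
    )
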