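"""Synthetic datasets with known planted structure.

Two generators cover the interesting regimes:

* :func:`make_planted_gradient` — sites strung along a chosen axis angle
  with a caterpillar tree whose leaf order matches the site order, so the
  true gradient admits a zero-crossing layout by construction (a
  caterpillar's consistent leaf orders are unique up to mirror image,
  making the planted signal unambiguous). Perpendicular jitter degrades
  other angles while preserving the ordering along the planted axis.
* :func:`make_null_dataset` — random coordinates and a uniformly random
  leaf-to-site assignment (no geographic signal), with optional injection
  of the degenerate configurations a sweep must survive: coincident
  sites, shared longitudes, collinear triples.

All outputs are deterministic given the seed and round-trip through the
geodata readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from geoaxes.geodata import (
    GeoTree,
    LocationSet,
    SampleSite,
    SequenceRecord,
    TreeNode,
)

__all__ = [
    "PlantedGradientSpec",
    "make_planted_gradient",
    "make_null_dataset",
    "make_count_table_data",
    "sequence_records",
]


@dataclass(frozen=True)
class PlantedGradientSpec:
    """Parameters of a planted linear gradient.

    ``planted_angle`` is the compass bearing (degrees, [0, 180)) of the
    axis along which the sites are laid out; ``scatter`` is the standard
    deviation of perpendicular jitter in coordinate units (site spacing
    along the axis is 1); ``mirrored`` reverses the caterpillar's leaf
    order relative to the site order, producing the worst-case fixed
    layout at the planted angle.
    """

    n_sites: int
    leaves_per_site: int = 1
    planted_angle: float = 90.0
    scatter: float = 0.0
    seed: int = 0
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3")
        if not (0.0 <= self.planted_angle < 180.0):
            raise ValueError("planted_angle must be in [0, 180)")
        if self.leaves_per_site < 1:
            raise ValueError("leaves_per_site must be >= 1")
        if self.scatter < 0:
            raise ValueError("scatter must be >= 0")


def _caterpillar(leaves: list[TreeNode]) -> TreeNode:
    """Right-combed caterpillar: (L1,(L2,(L3, ...)))."""
    node = leaves[-1]
    if len(leaves) >= 2:
        node = TreeNode(children=[leaves[-2], leaves[-1]])
        for leaf in leaves[-3::-1]:
            node = TreeNode(children=[leaf, node])
    return node


def make_planted_gradient(spec: PlantedGradientSpec
                          ) -> tuple[GeoTree, LocationSet]:
    """Generate a caterpillar tree and sites along a planted axis.

    Site k sits at arc position k (unit spacing) along the planted
    bearing, offset perpendicularly by N(0, scatter) jitter; coordinates
    are rescaled to stay well inside valid latitude/longitude ranges.
    The caterpillar's leaves follow the site order along the axis
    (reversed when ``mirrored``), so the optimal layout at the planted
    angle has zero crossings.
    """
    rng = np.random.default_rng(spec.seed)
    theta = math.radians(spec.planted_angle)
    u = np.array([math.sin(theta), math.cos(theta)])  # along-axis (x, y)
    v = np.array([math.cos(theta), -math.sin(theta)])  # perpendicular
    n = spec.n_sites
    t = np.arange(n, dtype=float)
    jitter = rng.normal(0.0, spec.scatter, size=n) if spec.scatter else \
        np.zeros(n)
    xy = np.outer(t - (n - 1) / 2.0, u) + np.outer(jitter, v)
    scale = 60.0 / max(1.0, float(np.abs(xy).max()))
    xy = xy * scale

    width = len(str(n))
    site_ids = [f"S{k + 1:0{width}d}" for k in range(n)]
    sites = [SampleSite(sid, latitude=float(y), longitude=float(x))
             for sid, (x, y) in zip(site_ids, xy)]
    locs = LocationSet(sites)

    leaf_nodes = []
    order = list(range(n))
    if spec.mirrored:
        order.reverse()
    for k in order:
        for rep in range(spec.leaves_per_site):
            if spec.leaves_per_site == 1:
                label = site_ids[k]
            else:
                label = f"{site_ids[k]}.{rep + 1}"
            leaf = TreeNode(label=label)
            leaf.site_id = site_ids[k]
            leaf_nodes.append(leaf)
    tree = GeoTree(_caterpillar(leaf_nodes))
    return tree, locs


def _random_topology(leaves: list[TreeNode], topology: str,
                     rng: np.random.Generator) -> TreeNode:
    if topology == "star":
        return TreeNode(children=leaves)
    nodes = list(leaves)
    while len(nodes) > 1:
        if topology == "random-binary":
            k = 2
        elif topology == "multifurcating":
            k = int(rng.integers(2, min(4, len(nodes)) + 1))
        else:
            raise ValueError(f"unknown topology {topology!r}")
        picks = rng.choice(len(nodes), size=k, replace=False)
        children = [nodes[i] for i in picks]
        for i in sorted(picks, reverse=True):
            nodes.pop(i)
        nodes.append(TreeNode(children=children))
    return nodes[0]


def make_null_dataset(
    n_sites: int,
    n_leaves: int,
    topology: str = "random-binary",
    seed: int = 0,
    degeneracies: tuple[str, ...] = (),
) -> tuple[GeoTree, LocationSet]:
    """Dataset with no geographic signal: random sites, random tree,
    uniform leaf-to-site assignment.

    ``degeneracies`` may include ``"duplicate"`` (sites 1 and 2 made
    coincident), ``"shared-longitude"`` (sites 1 and 2 on one meridian),
    and ``"collinear"`` (first three sites exactly collinear); these
    exercise the sweep's degenerate-event handling.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    if n_leaves < n_sites:
        raise ValueError("n_leaves must be >= n_sites")
    rng = np.random.default_rng(seed)
    # dyadic-grid coordinates: differences, doublings and cross products
    # are then exact in binary floating point, so injected collinearity
    # and parallelism are exact rather than approximate
    xy = rng.integers(0, 2 ** 20, size=(n_sites, 2)) / float(2 ** 20)
    for deg in degeneracies:
        if deg == "duplicate":
            xy[1] = xy[0]
        elif deg == "shared-longitude":
            xy[1, 0] = xy[0, 0]
        elif deg == "collinear" and n_sites >= 3:
            xy[2] = xy[0] + 2.0 * (xy[1] - xy[0])  # exact collinearity
        elif deg == "collinear":
            raise ValueError("collinear injection needs >= 3 sites")
        else:
            raise ValueError(f"unknown degeneracy {deg!r}")

    width = len(str(n_sites))
    site_ids = [f"S{k + 1:0{width}d}" for k in range(n_sites)]
    locs = LocationSet(
        SampleSite(sid, latitude=float(y), longitude=float(x))
        for sid, (x, y) in zip(site_ids, xy)
    )
    assignment = rng.integers(0, n_sites, size=n_leaves)
    leaf_width = len(str(n_leaves))
    leaves = []
    for i, site_idx in enumerate(assignment):
        leaf = TreeNode(label=f"q{i + 1:0{leaf_width}d}")
        leaf.site_id = site_ids[int(site_idx)]
        leaves.append(leaf)
    tree = GeoTree(_random_topology(leaves, topology, rng))
    return tree, locs


def sequence_records(tree: GeoTree) -> list[SequenceRecord]:
    """Sequence table mapping each leaf label to its resolved site."""
    return [
        SequenceRecord(leaf.label or "", leaf.site_id or "")
        for leaf in tree.leaves
    ]


def make_count_table_data(
    n_samples: int = 6,
    n_taxa: int = 12,
    seed: int = 0,
    mean_total: float = 200.0,
) -> "np.ndarray":
    """Random abundance matrix (lognormal taxon weights, Poisson counts);
    rows are guaranteed nonzero."""
    rng = np.random.default_rng(seed)
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=(n_samples, n_taxa))
    probs = weights / weights.sum(axis=1, keepdims=True)
    counts = rng.poisson(probs * mean_total)
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, int(rng.integers(n_taxa))] = 1
    return counts.astype(float)
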