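"""Shared helpers: tiny instance builders used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from geoaxes.geodata import (
    GeoTree,
    LocationSet,
    SampleSite,
    georeference,
    read_newick,
)
from geoaxes.sweep import SiteOrdering


def ordering_from_ids(site_ids, angle: float = 90.0) -> SiteOrdering:
    """SiteOrdering with the given site ids at distinct positions.

    An element of ``site_ids`` may itself be a tuple to form a tie group.
    """
    groups = tuple(
        tuple(sorted(s)) if isinstance(s, (tuple, list)) else (s,)
        for s in site_ids
    )
    return SiteOrdering(angle=angle, tie_groups=groups)


def line_locations(site_ids) -> LocationSet:
    """Sites strung west-to-east along the equator in the given order."""
    return LocationSet(
        SampleSite(sid, latitude=0.0, longitude=float(i))
        for i, sid in enumerate(site_ids)
    )


def tree_on_sites(newick: str, site_ids=None) -> GeoTree:
    """Parse a Newick string and georeference leaves to same-named sites."""
    tree = read_newick(newick)
    ids = site_ids if site_ids is not None else sorted(set(tree.leaf_labels))
    locs = line_locations(ids)
    return georeference(tree, locs)


def canonical_form(tree: GeoTree):
    """Order-independent canonical representation for isomorphism checks."""

    def rec(node):
        if node.is_leaf:
            return ("leaf", node.label)
        return ("node", tuple(sorted(rec(c) for c in node.children)))

    return rec(tree.root)


def random_instance(rng: np.random.Generator, max_leaves: int = 8,
                    allow_shared_sites: bool = True,
                    star_max_leaves: int = 6):
    """Random (tree, ordering) pair small enough for brute-force layout."""
    from geoaxes.synth import make_null_dataset
    from geoaxes.sweep import project_and_order

    topology = rng.choice(["random-binary", "multifurcating", "star"])
    if topology == "star":
        n_leaves = int(rng.integers(4, star_max_leaves + 1))
    else:
        n_leaves = int(rng.integers(4, max_leaves + 1))
    if allow_shared_sites and rng.random() < 0.5:
        n_sites = int(rng.integers(2, n_leaves + 1))
    else:
        n_sites = n_leaves
    tree, locs = make_null_dataset(
        n_sites, n_leaves, topology=str(topology),
        seed=int(rng.integers(2 ** 31)),
    )
    ordering = project_and_order(locs, float(rng.uniform(0.0, 180.0)))
    return tree, locs, ordering


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
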