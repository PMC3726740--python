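"""Domain types and file I/O: trees, sample sites, counts, dissimilarities.

Coordinates are treated as planar Cartesian throughout (x = longitude,
y = latitude, equirectangular): gradients are lines in the map plane, so no
great-circle geometry is used anywhere in the package.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SampleSite",
    "LocationSet",
    "SequenceRecord",
    "TreeNode",
    "GeoTree",
    "CountTable",
    "DissimilarityMatrix",
    "read_newick",
    "write_newick",
    "read_locations",
    "write_locations",
    "read_sequences",
    "read_count_table",
    "read_dissimilarity",
    "georeference",
    "GeodataError",
]


class GeodataError(ValueError):
    """Raised on malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Sites and locations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSite:
    """A georeferenced sample site.

    Parameters
    ----------
    site_id:
        Unique identifier within a :class:`LocationSet`.
    latitude, longitude:
        Decimal degrees; latitude in [-90, 90], longitude in [-180, 180].
    metadata:
        Arbitrary extra columns from the locations table.
    """

    site_id: str
    latitude: float
    longitude: float
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.site_id:
            raise GeodataError("site_id must be nonempty")
        if not (-90.0 <= self.latitude <= 90.0):
            raise GeodataError(
                f"latitude {self.latitude!r} of site {self.site_id!r} "
                "outside [-90, 90]"
            )
        if not (-180.0 <= self.longitude <= 180.0):
            raise GeodataError(
                f"longitude {self.longitude!r} of site {self.site_id!r} "
                "outside [-180, 180]"
            )

    @property
    def xy(self) -> tuple[float, float]:
        """Planar coordinates (x = longitude, y = latitude)."""
        return (self.longitude, self.latitude)


class LocationSet:
    """Ordered collection of :class:`SampleSite` with unique ids."""

    def __init__(self, sites: Iterable[SampleSite]):
        self.sites: list[SampleSite] = list(sites)
        self.id_index: dict[str, int] = {}
        for i, s in enumerate(self.sites):
            if s.site_id in self.id_index:
                raise GeodataError(f"duplicate site_id {s.site_id!r}")
            self.id_index[s.site_id] = i

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[SampleSite]:
        return iter(self.sites)

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.id_index

    def __getitem__(self, site_id: str) -> SampleSite:
        return self.sites[self.id_index[site_id]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocationSet):
            return NotImplemented
        return self.sites == other.sites

    @property
    def ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of planar coordinates (x = lon, y = lat)."""
        return np.array([s.xy for s in self.sites], dtype=float)

    def __repr__(self) -> str:
        return f"LocationSet({len(self)} sites)"


@dataclass(frozen=True)
class SequenceRecord:
    """A sequence observed at a site (taxonomy etc. in ``attributes``)."""

    sequence_id: str
    site_id: str
    attributes: Mapping[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of a rooted, possibly multifurcating tree.

    Leaves carry a ``label`` and, after georeferencing, a resolved
    ``site_id``. Branch lengths are retained but ignored by every layout
    computation.
    """

    __slots__ = ("label", "children", "length", "site_id", "index")

    def __init__(
        self,
        label: str | None = None,
        children: list["TreeNode"] | None = None,
        length: float | None = None,
    ):
        self.label = label
        self.children: list[TreeNode] = children or []
        self.length = length
        self.site_id: str | None = None
        self.index: int = -1  # preorder index, set by GeoTree

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GeoTree:
    """Rooted tree whose leaves map to sample sites.

    Internal nodes have >= 2 children (multifurcations allowed); the tree
    has >= 2 leaves. ``georeferenced`` is True once every leaf carries a
    resolved ``site_id``.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._reindex()
        if len(self.leaves) < 2:
            raise GeodataError("tree must have at least 2 leaves")
        for node in self.nodes:
            if node.children and len(node.children) < 2:
                raise GeodataError(
                    "internal nodes must have >= 2 children "
                    "(unifurcation found)"
                )

    def _reindex(self) -> None:
        self.nodes: list[TreeNode] = []
        self.leaves: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            node.index = len(self.nodes)
            self.nodes.append(node)
            if node.is_leaf:
                self.leaves.append(node)
            stack.extend(reversed(node.children))
        # preorder push/pop above yields preorder indices; leaves in
        # left-to-right order
        self.leaves.sort(key=lambda n: n.index)

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.label or "" for leaf in self.leaves]

    @property
    def georeferenced(self) -> bool:
        return all(leaf.site_id is not None for leaf in self.leaves)

    def leaf_site_ids(self) -> list[str]:
        if not self.georeferenced:
            raise GeodataError("tree is not georeferenced")
        return [leaf.site_id for leaf in self.leaves]  # type: ignore[misc]

    def copy(self) -> "GeoTree":
        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(node.label, [clone(ch) for ch in node.children],
                         node.length)
            c.site_id = node.site_id
            return c

        return GeoTree(clone(self.root))

    def __repr__(self) -> str:
        return (
            f"GeoTree({len(self.leaves)} leaves, "
            f"georeferenced={self.georeferenced})"
        )


def _from_dendropy(node: dendropy.Node) -> TreeNode:
    if node.is_leaf():
        label = node.taxon.label if node.taxon is not None else node.label
        return TreeNode(label=label, length=node.edge.length)
    children = [_from_dendropy(c) for c in node.child_nodes()]
    return TreeNode(label=node.label, children=children,
                    length=node.edge.length)


def read_newick(text: str) -> GeoTree:
    """Parse a Newick string into an (ungeoreferenced) :class:`GeoTree`.

    Multifurcations are preserved as-is; branch lengths and internal node
    labels are kept but unused by layout computations.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            # labels stay plain node labels: several leaves may legally
            # carry the same site id
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise GeodataError(f"Newick parse error: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    # dendropy may wrap a single-child root; collapse unifurcations at root
    while len(root.children) == 1:
        root = root.children[0]
    return GeoTree(root)


def _newick_label(label: str | None) -> str:
    if not label:
        return ""
    if any(ch in label for ch in "():;, \t'\"[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: GeoTree, with_lengths: bool = True) -> str:
    """Serialize a :class:`GeoTree` to a Newick string."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = _newick_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            s += _newick_label(node.label)
        if with_lengths and node.length is not None:
            s += f":{node.length:g}"
        return s

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

_ID_ALIASES = {"site id", "siteid", "site_id", "id"}
_LAT_ALIASES = {"latitude", "lat"}
_LON_ALIASES = {"longitude", "lon", "long"}


def _match_column(columns: Sequence[str], aliases: set[str]) -> str | None:
    for col in columns:
        if str(col).strip().lower() in aliases:
            return col
    return None


def _read_csv(source) -> pd.DataFrame:
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    return pd.read_csv(source, dtype=object)


def read_locations(source) -> LocationSet:
    """Read a locations table (CSV path, file object, or CSV text).

    The header must contain a site-id, latitude and longitude column
    (case- and whitespace-insensitive aliases accepted); all other columns
    are preserved as per-site metadata.
    """
    df = _read_csv(source)
    id_col = _match_column(df.columns, _ID_ALIASES)
    lat_col = _match_column(df.columns, _LAT_ALIASES)
    lon_col = _match_column(df.columns, _LON_ALIASES)
    missing = [name for name, col in
               (("site id", id_col), ("latitude", lat_col),
                ("longitude", lon_col)) if col is None]
    if missing:
        raise GeodataError(
            f"locations table is missing mandatory column(s): "
            f"{', '.join(missing)}"
        )
    meta_cols = [c for c in df.columns if c not in (id_col, lat_col, lon_col)]
    sites = []
    for _, row in df.iterrows():
        site_id = str(row[id_col]).strip()
        try:
            lat = float(row[lat_col])
            lon = float(row[lon_col])
        except (TypeError, ValueError) as exc:
            raise GeodataError(
                f"non-numeric coordinate for site {site_id!r}: "
                f"lat={row[lat_col]!r} lon={row[lon_col]!r}"
            ) from exc
        if not (math.isfinite(lat) and math.isfinite(lon)):
            raise GeodataError(f"non-finite coordinate for site {site_id!r}")
        metadata = {c: row[c] for c in meta_cols}
        sites.append(SampleSite(site_id, lat, lon, metadata))
    return LocationSet(sites)


def write_locations(locs: LocationSet, path) -> None:
    """Write a locations table as CSV (site_id, latitude, longitude, meta)."""
    meta_cols: list[str] = []
    for s in locs:
        for k in s.metadata:
            if k not in meta_cols:
                meta_cols.append(k)
    rows = []
    for s in locs:
        row = {"site_id": s.site_id, "latitude": s.latitude,
               "longitude": s.longitude}
        row.update({k: s.metadata.get(k, "") for k in meta_cols})
        rows.append(row)
    pd.DataFrame(rows, columns=["site_id", "latitude", "longitude",
                                *meta_cols]).to_csv(path, index=False)


_SEQ_ID_ALIASES = {"sequence id", "sequenceid", "sequence_id", "seq_id", "id"}


def read_sequences(source) -> list[SequenceRecord]:
    """Read a sequences table mapping sequence ids to site ids."""
    df = _read_csv(source)
    seq_col = _match_column(df.columns, _SEQ_ID_ALIASES)
    site_col = _match_column(df.columns, _ID_ALIASES - {"id"})
    if seq_col is None or site_col is None:
        raise GeodataError(
            "sequences table needs a sequence-id column and a site-id column"
        )
    records = []
    for _, row in df.iterrows():
        attrs = {c: row[c] for c in df.columns if c not in (seq_col, site_col)}
        records.append(SequenceRecord(str(row[seq_col]).strip(),
                                      str(row[site_col]).strip(), attrs))
    return records


# ---------------------------------------------------------------------------
# Count tables and dissimilarity matrices
# ---------------------------------------------------------------------------

class CountTable:
    """Sites-or-samples x taxa abundance matrix (nonnegative)."""

    def __init__(self, data: pd.DataFrame):
        values = data.to_numpy(dtype=float)
        if np.any(values < 0):
            raise GeodataError("count table contains negative entries")
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise GeodataError("count table row/column ids must be unique")
        self.data = data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @classmethod
    def read_csv(cls, source) -> "CountTable":
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        return cls(pd.read_csv(source, index_col=0))

    def to_csv(self, path) -> None:
        self.data.to_csv(path)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"CountTable({self.data.shape[0]} samples x " \
               f"{self.data.shape[1]} taxa)"


def read_count_table(source) -> CountTable:
    return CountTable.read_csv(source)


class DissimilarityMatrix:
    """Square symmetric dissimilarity matrix with labelled axes."""

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise GeodataError(
                f"matrix shape {values.shape} does not match {n} ids"
            )
        if len(set(ids)) != n:
            raise GeodataError("dissimilarity matrix ids must be unique")
        if not np.allclose(values, values.T, atol=1e-9):
            raise GeodataError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-9):
            raise GeodataError("dissimilarity matrix must have zero diagonal")
        if np.any(values < -1e-12):
            raise GeodataError("dissimilarity values must be >= 0")
        self.ids = [str(i) for i in ids]
        self.values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def read_csv(cls, source) -> "DissimilarityMatrix":
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        df = pd.read_csv(source, index_col=0)
        ids = [str(i) for i in df.index]
        if [str(c) for c in df.columns] != ids:
            raise GeodataError(
                "dissimilarity CSV row and column labels must match"
            )
        return cls(ids, df.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids,
                     columns=self.ids).to_csv(path)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) entries in row-major order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def __repr__(self) -> str:
        return f"DissimilarityMatrix({len(self.ids)} ids)"


def read_dissimilarity(source) -> DissimilarityMatrix:
    return DissimilarityMatrix.read_csv(source)


# ---------------------------------------------------------------------------
# Georeferencing
# ---------------------------------------------------------------------------

def georeference(
    tree: GeoTree,
    locs: LocationSet,
    seqs: Sequence[SequenceRecord] | None = None,
) -> GeoTree:
    """Resolve every leaf label to a site id.

    A leaf label is matched against site ids first, then against sequence
    ids (whose records name a site). A label matching both a site and a
    *different* site through a sequence record is ambiguous and raises.
    Returns a new georeferenced tree; the input is not modified.
    Idempotent: applying it twice yields the same mapping.
    """
    seq_index: dict[str, str] = {}
    if seqs:
        for rec in seqs:
            if rec.site_id not in locs:
                raise GeodataError(
                    f"sequence {rec.sequence_id!r} references unknown "
                    f"site {rec.site_id!r}"
                )
            if (rec.sequence_id in seq_index
                    and seq_index[rec.sequence_id] != rec.site_id):
                raise GeodataError(
                    f"sequence id {rec.sequence_id!r} maps to multiple sites"
                )
            seq_index[rec.sequence_id] = rec.site_id

    out = tree.copy()
    unmatched: list[str] = []
    for leaf in out.leaves:
        label = leaf.label or ""
        site = locs.id_index.get(label)
        via_seq = seq_index.get(label)
        if site is not None:
            if via_seq is not None and via_seq != label:
                raise GeodataError(
                    f"leaf {label!r} is ambiguous: matches site {label!r} "
                    f"and site {via_seq!r} via the sequence table"
                )
            leaf.site_id = label
        elif via_seq is not None:
            leaf.site_id = via_seq
        else:
            unmatched.append(label)
    if unmatched:
        raise GeodataError(
            "unmatched leaf label(s): " + ", ".join(repr(u) for u in unmatched)
        )
    return out
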