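"""Linear axes analysis: crossing number as a function of axis angle.

A linear geographic axis at compass bearing theta (0 deg = due north,
90 deg = due east) orders sample sites by their scalar projection onto the
axis direction. As the axis rotates, the ordering changes only at
*critical angles*, where the line through some pair of sites becomes
perpendicular to the axis; between consecutive critical angles the
ordering — and hence the minimum crossing number of the tree layout — is
constant. Because an axis and its reverse induce the same (undirected)
gradient, the profile has period 180 deg and is computed on [0, 180).

Degenerate configurations are handled symbolically rather than by
numerical nudging: at an angle where projections tie exactly, sites are
ordered as they would appear just after an infinitesimal clockwise
rotation (the derivative of the projection with respect to the bearing is
the secondary sort key). Coincident sites tie at every angle and form
permanent tie groups, ordered internally by site id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from geoaxes.geodata import GeoTree, LocationSet
from geoaxes.layout import CompiledTree, minimum_crossings

__all__ = [
    "SiteOrdering",
    "SweepEvent",
    "SweepInterval",
    "SweepProfile",
    "project_and_order",
    "critical_angles",
    "linear_axes_analysis",
]

# Relative tolerance for "exactly equal" projections; differences below
# coordinate_scale * _TIE_RTOL are ties resolved by the rotation rule.
_TIE_RTOL = 1e-9
# Critical angles closer than this (degrees) are merged into one event,
# absorbing floating-point slope collisions of parallel/collinear pairs.
_ANGLE_MERGE_TOL_DEG = 1e-9


@dataclass(frozen=True)
class SiteOrdering:
    """Total order of site ids induced by an axis angle, with tie groups.

    ``tie_groups`` partitions the site ids: group k contains the sites at
    ordering position k; only sites with exactly equal projection (in
    practice: coincident coordinates, or exact ties at a critical angle
    that the rotation rule cannot separate) share a group.
    """

    angle: float
    tie_groups: tuple[tuple[str, ...], ...]
    position: dict[str, int] = field(repr=False, compare=False, hash=False,
                                     default_factory=dict)

    def __post_init__(self) -> None:
        if not self.position:
            pos = {}
            for k, group in enumerate(self.tie_groups):
                for sid in group:
                    pos[sid] = k
            object.__setattr__(self, "position", pos)

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(sid for group in self.tie_groups for sid in group)

    @property
    def n_positions(self) -> int:
        return len(self.tie_groups)

    def __len__(self) -> int:
        return len(self.position)


@dataclass(frozen=True)
class SweepEvent:
    """A critical angle and the site pairs whose order flips there."""

    angle: float
    swapping_pairs: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class SweepInterval:
    """Half-open angular interval [start, end) of constant crossings."""

    angle_start: float
    angle_end: float
    crossings: int
    ordering: SiteOrdering

    def __contains__(self, angle: float) -> bool:
        a = angle % 180.0
        return self.angle_start <= a < self.angle_end


@dataclass(frozen=True)
class SweepProfile:
    """Piecewise-constant crossing-count function over [0, 180)."""

    intervals: tuple[SweepInterval, ...]
    events: tuple[SweepEvent, ...]

    @property
    def min_crossings(self) -> int:
        return min(iv.crossings for iv in self.intervals)

    @property
    def max_crossings(self) -> int:
        return max(iv.crossings for iv in self.intervals)

    @property
    def argmin_intervals(self) -> tuple[SweepInterval, ...]:
        m = self.min_crossings
        return tuple(iv for iv in self.intervals if iv.crossings == m)

    @property
    def argmax_intervals(self) -> tuple[SweepInterval, ...]:
        m = self.max_crossings
        return tuple(iv for iv in self.intervals if iv.crossings == m)

    def value_at(self, angle: float) -> int:
        """Crossing number of the interval containing ``angle`` (mod 180)."""
        a = angle % 180.0
        for iv in self.intervals:
            if iv.angle_start <= a < iv.angle_end:
                return iv.crossings
        raise ValueError(f"angle {angle} not covered by the profile")

    def interval_at(self, angle: float) -> SweepInterval:
        a = angle % 180.0
        for iv in self.intervals:
            if iv.angle_start <= a < iv.angle_end:
                return iv
        raise ValueError(f"angle {angle} not covered by the profile")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "angle_start_deg": [iv.angle_start for iv in self.intervals],
                "angle_end_deg": [iv.angle_end for iv in self.intervals],
                "crossings": [iv.crossings for iv in self.intervals],
            }
        )


# ---------------------------------------------------------------------------
# Projection and ordering
# ---------------------------------------------------------------------------

def project_and_order(locs: LocationSet, angle: float) -> SiteOrdering:
    """Order sites by scalar projection onto the axis at ``angle``.

    The bearing is normalized mod 180 (an axis and its reverse define the
    same undirected gradient). Ties are broken by the projection
    derivative — the ordering just after an infinitesimal clockwise
    rotation — and sites tied in both (coincident coordinates) form a tie
    group, internally sorted by site id.
    """
    if len(locs) == 0:
        raise ValueError("empty LocationSet")
    a = angle % 180.0
    theta = math.radians(a)
    s, c = math.sin(theta), math.cos(theta)
    coords = locs.coordinates()
    proj = coords[:, 0] * s + coords[:, 1] * c
    dproj = coords[:, 0] * c - coords[:, 1] * s  # d(proj)/d(theta)
    scale = max(1.0, float(abs(coords).max())) if len(locs) else 1.0
    tol = scale * _TIE_RTOL

    idx = sorted(range(len(locs)), key=lambda i: proj[i])
    groups: tuple[tuple[str, ...], ...] = tuple(
        _order_tied(block, dproj, tol, locs)
        for block in _split_adjacent(idx, proj, tol)
    )
    flat = tuple(g for block in groups for g in block)
    return SiteOrdering(angle=a, tie_groups=flat)


def _split_adjacent(idx: list[int], key, tol: float) -> list[list[int]]:
    """Group sorted indices whose consecutive key gaps are within tol."""
    blocks: list[list[int]] = []
    for i in idx:
        if blocks and key[i] - key[blocks[-1][-1]] <= tol:
            blocks[-1].append(i)
        else:
            blocks.append([i])
    return blocks


def _order_tied(block: list[int], dproj, tol: float,
                locs: LocationSet) -> tuple[tuple[str, ...], ...]:
    """Resolve a projection tie: sort by derivative, then group coincident
    sites (tied in value and derivative) into tie groups sorted by id."""
    if len(block) == 1:
        return ((locs.sites[block[0]].site_id,),)
    block = sorted(block, key=lambda i: dproj[i])
    out = []
    for sub in _split_adjacent(block, dproj, tol):
        ids = sorted(locs.sites[i].site_id for i in sub)
        out.append(tuple(ids))
    return tuple(out)


# ---------------------------------------------------------------------------
# Critical angles
# ---------------------------------------------------------------------------

def critical_angles(locs: LocationSet) -> list[SweepEvent]:
    """All angles in [0, 180) where the site ordering changes.

    One event per distinct perpendicular direction over all site pairs:
    the pair (i, j) flips exactly when the axis is perpendicular to the
    segment i-j. Coincident pairs generate no event; pairs with equal
    slope (parallel segments, collinear triples) merge into one event.
    """
    if len(locs) < 2:
        raise ValueError("need at least 2 sites")
    coords = locs.coordinates()
    ids = locs.ids
    raw: list[tuple[float, tuple[str, str]]] = []
    n = len(locs)
    for i in range(n):
        for j in range(i + 1, n):
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            if dx == 0.0 and dy == 0.0:
                continue  # coincident sites never swap
            ang = math.degrees(math.atan2(-dy, dx)) % 180.0
            raw.append((ang, (ids[i], ids[j])))
    if not raw:
        return []
    raw.sort(key=lambda t: t[0])
    events: list[tuple[float, list[tuple[str, str]]]] = []
    for ang, pair in raw:
        if events and ang - events[-1][0] <= _ANGLE_MERGE_TOL_DEG:
            events[-1][1].append(pair)
        else:
            events.append((ang, [pair]))
    # wrap-around: an event within tolerance of 180 coincides with 0
    if len(events) > 1 and (events[0][0] + 180.0 - events[-1][0]
                            <= _ANGLE_MERGE_TOL_DEG):
        last = events.pop()
        events[0][1].extend(last[1])
    elif len(events) == 1 and events[0][0] > 180.0 - _ANGLE_MERGE_TOL_DEG:
        events[0] = (0.0, events[0][1])
    return [SweepEvent(angle=a, swapping_pairs=tuple(pairs))
            for a, pairs in events]


# ---------------------------------------------------------------------------
# The sweep itself
# ---------------------------------------------------------------------------

def linear_axes_analysis(tree: GeoTree, locs: LocationSet) -> SweepProfile:
    """Crossing-number profile of ``tree`` over every linear axis.

    The events of :func:`critical_angles` partition [0, 180) into
    intervals of constant site ordering; on each interval the ordering is
    taken just after the opening event (clockwise-rotation rule) and the
    globally optimal layout is computed. Exact by construction: every
    attainable ordering is evaluated once.
    """
    events = critical_angles(locs)
    compiled = CompiledTree(tree)
    boundaries = [e.angle for e in events]
    if not boundaries or boundaries[0] > 0.0:
        boundaries = [0.0] + boundaries
    ends = boundaries[1:] + [180.0]
    intervals = []
    for start, end in zip(boundaries, ends):
        ordering = project_and_order(locs, start)
        positions = compiled.positions_for(ordering)
        crossings = minimum_crossings(compiled, positions)
        intervals.append(SweepInterval(start, end, crossings, ordering))
    return SweepProfile(intervals=tuple(intervals), events=tuple(events))


def evaluate_axis(tree: GeoTree, locs: LocationSet, angle: float) -> int:
    """Direct minimum-crossing evaluation at a single axis angle.

    Independent of the sweep bookkeeping; used as its oracle.
    """
    compiled = CompiledTree(tree)
    ordering = project_and_order(locs, angle)
    return minimum_crossings(compiled, compiled.positions_for(ordering))
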