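"""Territory polygons, disperser detection and telemetry overlap.

Each genetic group's territory is the minimum convex polygon (``P_total``)
over the spatially coherent core of its members (individuals with membership
above 0.5 to the group, chained by single-linkage at an adjacency distance);
``P_non_admixed`` is the hull of the core's non-admixed members only. A
disperser is a non-admixed individual located outside its own group's
``P_total``; its host is the group whose polygon contains it, if any.
Collared animals get a ``P_s`` hull over all telemetry locations of their
full monitoring period, and the number of group territories each ``P_s``
overlaps is counted.

All geometry is planar (projected coordinates, km; areas in km²).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, mapping
from shapely.geometry.base import BaseGeometry

from .admixture import QMatrix
from .classify import NON_ADMIXED, UNASSIGNED, ClusterPartition
from .data import SampleMetadata, TrackRecord, ValidationError, metadata_index


# ---------------------------------------------------------------------------
# group polygons
# ---------------------------------------------------------------------------

@dataclass
class DisperserRecord:
    sample_id: str
    source_group: int
    host_group: int | None  # None: location overlaps no group polygon


@dataclass
class GroupShape:
    group: int
    p_total: BaseGeometry | None  # None when degenerate (<3 non-collinear pts)
    p_non_admixed: BaseGeometry | None
    core_ids: list[str]
    outlier_ids: list[str]  # members outside the largest spatial block
    degenerate: bool = False

    @property
    def area_total(self) -> float:
        return float(self.p_total.area) if self.p_total is not None else np.nan

    @property
    def area_non_admixed(self) -> float:
        return float(self.p_non_admixed.area) if self.p_non_admixed is not None else np.nan


@dataclass
class GroupGeometry:
    shapes: list[GroupShape]
    dispersers: list[DisperserRecord] = field(default_factory=list)

    def shape(self, group: int) -> GroupShape:
        return self.shapes[group]


def _single_linkage_blocks(xy: np.ndarray, cutoff: float) -> list[list[int]]:
    """Partition points into single-linkage chains at the cutoff distance."""
    n = len(xy)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(xy[i] - xy[j])) <= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    blocks: dict[int, list[int]] = {}
    for i in range(n):
        blocks.setdefault(find(i), []).append(i)
    return sorted(blocks.values(), key=lambda b: (-len(b), b[0]))


def _hull(points: np.ndarray) -> tuple[BaseGeometry | None, bool]:
    """Convex hull; returns (polygon, degenerate) — degenerate when the hull
    collapses to a point or segment."""
    if len(points) < 3:
        return None, True
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0:
        return None, True
    return hull, False


def build_group_polygons(
    partition: ClusterPartition,
    metadata: list[SampleMetadata],
    adjacency_km: float = 50.0,
) -> GroupGeometry:
    """Build P_total and P_non_admixed for every group.

    For each group, members with q above 0.5 are chained by single linkage at
    ``adjacency_km``; the largest chain is the territory core, whose hull is
    ``P_total``. Members outside the core are recorded as outliers (candidate
    dispersers or unplaceable individuals). Groups whose core has fewer than
    three non-collinear placeable points get a degenerate (None) geometry and
    are flagged.
    """
    meta = metadata_index(metadata)
    missing = [s for s in partition.sample_ids if s not in meta]
    if missing:
        raise ValidationError(f"no metadata for classified sample(s): {missing[:5]}")
    shapes: list[GroupShape] = []
    for k in range(partition.K):
        ids = [
            sid
            for sid, home, lab in zip(
                partition.sample_ids, partition.home_cluster, partition.labels
            )
            if home == k and lab != UNASSIGNED
        ]
        if not ids:
            shapes.append(GroupShape(k, None, None, [], [], degenerate=True))
            continue
        xy = np.array([(meta[s].x, meta[s].y) for s in ids])
        blocks = _single_linkage_blocks(xy, adjacency_km)
        core = blocks[0]
        core_ids = [ids[i] for i in core]
        outliers = [ids[i] for b in blocks[1:] for i in b]
        p_total, degenerate = _hull(xy[core])
        if degenerate:
            warnings.warn(
                f"group {k}: degenerate territory (<3 non-collinear core points)",
                stacklevel=2,
            )
        na_ids = set(partition.non_admixed_ids(k))
        na_points = np.array(
            [(meta[s].x, meta[s].y) for s in core_ids if s in na_ids]
        ).reshape(-1, 2)
        p_na, _ = _hull(na_points)
        shapes.append(
            GroupShape(k, p_total, p_na, core_ids, outliers, degenerate=degenerate)
        )
    geometry = GroupGeometry(shapes=shapes)
    geometry.dispersers = detect_dispersers(partition, geometry, metadata)
    return geometry


def detect_dispersers(
    partition: ClusterPartition,
    geometry: GroupGeometry,
    metadata: list[SampleMetadata],
) -> list[DisperserRecord]:
    """Non-admixed individuals located outside their own group's P_total.

    The host is the group whose P_total contains the individual's location,
    or None when the location overlaps no group polygon.
    """
    meta = metadata_index(metadata)
    records: list[DisperserRecord] = []
    for sid, home, lab in zip(
        partition.sample_ids, partition.home_cluster, partition.labels
    ):
        if lab != NON_ADMIXED:
            continue
        own = geometry.shape(int(home)).p_total
        pt = Point(meta[sid].x, meta[sid].y)
        if own is not None and own.covers(pt):
            continue
        host = None
        for shape in geometry.shapes:
            if shape.group == home or shape.p_total is None:
                continue
            if shape.p_total.covers(pt):
                host = shape.group
                break
        records.append(DisperserRecord(sid, int(home), host))
    return records


# ---------------------------------------------------------------------------
# group summaries (Table 1/2-shaped)
# ---------------------------------------------------------------------------

def group_summary(
    q: QMatrix,
    partition: ClusterPartition,
    geometry: GroupGeometry,
    metadata: list[SampleMetadata],
    contribution_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-group composition summary.

    Columns: member count, count of external groups contributing strictly
    more than the threshold to the group's mean membership, admixed count and
    fraction, dispersers received, fraction of members inside P_non_admixed,
    P_non_admixed/P_total area ratio, and the smallest Euclidean distance
    between the group's P_total border and any other group's (0 when they
    overlap, NaN for degenerate geometry).
    """
    meta = metadata_index(metadata)
    sizes = partition.group_sizes()
    admixed = partition.admixed_counts()
    received = np.zeros(partition.K, dtype=int)
    for rec in geometry.dispersers:
        if rec.host_group is not None:
            received[rec.host_group] += 1
    rows = []
    for k in range(partition.K):
        shape = geometry.shape(k)
        mean_row = partition.mean_membership[k]
        if np.all(np.isnan(mean_row)):
            contributing = 0
        else:
            contributing = int(
                sum(
                    1
                    for kk in range(partition.K)
                    if kk != k and mean_row[kk] > contribution_threshold
                )
            )
        member_ids = [
            sid
            for sid, home, lab in zip(
                partition.sample_ids, partition.home_cluster, partition.labels
            )
            if home == k and lab != UNASSIGNED
        ]
        if shape.p_non_admixed is not None and member_ids:
            inside = sum(
                1
                for sid in member_ids
                if shape.p_non_admixed.covers(Point(meta[sid].x, meta[sid].y))
            )
            frac_inside = inside / len(member_ids)
        else:
            frac_inside = np.nan
        if shape.p_total is not None:
            dists = [
                shape.p_total.distance(other.p_total)
                for other in geometry.shapes
                if other.group != k and other.p_total is not None
            ]
            nearest = float(min(dists)) if dists else np.nan
        else:
            nearest = np.nan
        area_ratio = (
            shape.area_non_admixed / shape.area_total
            if shape.p_total is not None and shape.p_non_admixed is not None
            else np.nan
        )
        rows.append(
            {
                "group": k,
                "n": int(sizes[k]),
                "contributing_groups_gt5pct": contributing,
                "admixed_count": int(admixed[k]),
                "admixed_fraction": admixed[k] / sizes[k] if sizes[k] else np.nan,
                "dispersers_received": int(received[k]),
                "fraction_inside_p_non_admixed": frac_inside,
                "area_ratio_na_total": area_ratio,
                "nearest_border_km": nearest,
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# telemetry overlap
# ---------------------------------------------------------------------------

def track_mcp_overlap(
    tracks: list[TrackRecord],
    geometry: GroupGeometry,
    min_overlap_fraction: float = 0.01,
) -> pd.DataFrame:
    """Full-monitoring MCP (P_s) per animal and the number of group
    territories it overlaps.

    A group counts as overlapped when the intersection area is at least
    ``min_overlap_fraction`` of the P_s area (a guard against boundary-touch
    artifacts; 0 restores a strict any-intersection rule). Tracks with fewer
    than three non-collinear locations are flagged degenerate; for those,
    overlap falls back to point-in-polygon counting.
    """
    if not geometry.shapes:
        raise ValueError("empty group geometry")
    rows = []
    for tr in tracks:
        xy = tr.xy()
        hull, degenerate = _hull(xy)
        overlapped = []
        if hull is not None:
            area = hull.area
            for shape in geometry.shapes:
                if shape.p_total is None:
                    continue
                inter = hull.intersection(shape.p_total).area
                if min_overlap_fraction > 0:
                    if inter >= min_overlap_fraction * area:
                        overlapped.append(shape.group)
                elif inter > 0 or hull.intersects(shape.p_total):
                    overlapped.append(shape.group)
        else:
            pts = [Point(*p) for p in xy]
            for shape in geometry.shapes:
                if shape.p_total is not None and any(
                    shape.p_total.covers(p) for p in pts
                ):
                    overlapped.append(shape.group)
        rows.append(
            {
                "animal_id": tr.animal_id,
                "n_locations": len(tr.locations),
                "monitoring_days": tr.monitoring_days,
                "mcp_area_km2": float(hull.area) if hull is not None else 0.0,
                "degenerate": degenerate,
                "n_groups_overlapped": len(overlapped),
                "groups_overlapped": overlapped,
            }
        )
    return pd.DataFrame(rows).set_index("animal_id")


# ---------------------------------------------------------------------------
# polygon export
# ---------------------------------------------------------------------------

def polygons_to_geojson(geometry: GroupGeometry, path: str | Path) -> None:
    """Write P_total / P_non_admixed polygons as one GeoJSON FeatureCollection."""
    features = []
    for shape in geometry.shapes:
        for level, poly in (("P_total", shape.p_total), ("P_non_admixed", shape.p_non_admixed)):
            if poly is None:
                continue
            features.append(
                {
                    "type": "Feature",
                    "properties": {"group": shape.group, "level": level,
                                   "area_km2": poly.area},
                    "geometry": mapping(poly),
                }
            )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=2)
    )


def polygons_to_wkt(geometry: GroupGeometry, path: str | Path) -> None:
    """Write polygons as a WKT CSV (group, level, area_km2, wkt)."""
    rows = []
    for shape in geometry.shapes:
        for level, poly in (("P_total", shape.p_total), ("P_non_admixed", shape.p_non_admixed)):
            if poly is not None:
                rows.append((shape.group, level, poly.area, poly.wkt))
    pd.DataFrame(rows, columns=["group", "level", "area_km2", "wkt"]).to_csv(
        path, index=False
    )
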