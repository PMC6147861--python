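"""Territory polygons, disperser logic and telemetry overlap."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import MultiPoint

from lupine import (
    QMatrix,
    SampleMetadata,
    TrackRecord,
    build_group_polygons,
    classify_individuals,
    group_summary,
    track_mcp_overlap,
)
from lupine.spatial import _single_linkage_blocks


def _partition(q_rows, cutoffs=None):
    q = np.asarray(q_rows, dtype=float)
    qm = QMatrix(K=q.shape[1], q=q, ln_prob_data=0.0,
                 sample_ids=[f"s{i}" for i in range(len(q))])
    K = q.shape[1]
    return classify_individuals(qm, np.full(K, cutoffs or 0.8)), qm


def _meta(points):
    return [
        SampleMetadata(f"s{i}", x=float(x), y=float(y),
                       collection_date=dt.date(2005, 1, 1))
        for i, (x, y) in enumerate(points)
    ]


def test_unit_square_hull_area():
    part, _ = _partition([[0.95, 0.05]] * 4)
    meta = _meta([(0, 0), (1, 0), (1, 1), (0, 1)])
    geom = build_group_polygons(part, meta)
    assert geom.shape(0).area_total == pytest.approx(1.0)
    assert geom.shape(0).p_non_admixed.area == pytest.approx(1.0)


def test_far_member_becomes_candidate_disperser():
    # 4 members of cluster 0 in a square; a 5th cluster-0 member 300 km away,
    # inside cluster 1's hull
    q = [[0.95, 0.05]] * 5 + [[0.05, 0.95]] * 4
    part, _ = _partition(q)
    pts = [(0, 0), (1, 0), (1, 1), (0, 1), (300, 0.5),
           (299, -1), (301, -1), (301, 2), (299, 2)]
    geom = build_group_polygons(_partition(q)[0], _meta(pts))
    assert "s4" in geom.shape(0).outlier_ids
    recs = {d.sample_id: d for d in geom.dispersers}
    assert recs["s4"].source_group == 0
    assert recs["s4"].host_group == 1


def test_disperser_outside_every_hull_has_no_host():
    q = [[0.95, 0.05]] * 5 + [[0.05, 0.95]] * 3
    pts = [(0, 0), (1, 0), (1, 1), (0, 1), (500, 500),
           (300, 0), (301, 0), (300, 1)]
    geom = build_group_polygons(_partition(q)[0], _meta(pts))
    recs = {d.sample_id: d for d in geom.dispersers}
    assert recs["s4"].host_group is None


def test_no_dispersers_when_everyone_is_home(wolf_shaped):
    _, table, metadata, truth = wolf_shaped
    # strip the planted dispersers: everyone lives in their genetic home
    keep = [table.sample_ids[i] for i in np.flatnonzero(~truth.is_disperser)]
    q = truth.true_q[~truth.is_disperser]
    qm = QMatrix(K=q.shape[1],
                 q=np.maximum(q, 1e-12) / np.maximum(q, 1e-12).sum(1, keepdims=True),
                 ln_prob_data=0.0, sample_ids=keep)
    part = classify_individuals(qm, np.full(q.shape[1], 0.8))
    meta = [m for m in metadata if m.sample_id in set(keep)]
    geom = build_group_polygons(part, meta)
    assert geom.dispersers == []


def test_disperser_counts_are_conserved(wolf_shaped):
    _, table, metadata, truth = wolf_shaped
    q = np.maximum(truth.true_q, 1e-12)
    qm = QMatrix(K=q.shape[1], q=q / q.sum(1, keepdims=True),
                 ln_prob_data=0.0, sample_ids=table.sample_ids)
    part = classify_individuals(qm, np.full(q.shape[1], 0.8))
    geom = build_group_polygons(part, metadata)
    summ = group_summary(qm, part, geom, metadata)
    hosted = int(summ.dispersers_received.sum())
    unhosted = sum(1 for d in geom.dispersers if d.host_group is None)
    assert hosted + unhosted == len(geom.dispersers)


def test_contributing_groups_counted_above_strict_5pct():
    # mean membership row (0.89, 0.04, 0.06, 0.01): one external group > 5%
    rows = [[0.89, 0.04, 0.06, 0.01]] * 3
    rows += [[0.04, 0.9, 0.03, 0.03], [0.02, 0.02, 0.94, 0.02], [0.01, 0.01, 0.03, 0.95]]
    part, qm = _partition(rows, cutoffs=0.99)
    pts = [(0, 0), (1, 0), (0.5, 1), (100, 0), (200, 0), (300, 0)]
    geom = build_group_polygons(part, _meta(pts))
    summ = group_summary(qm, part, geom, _meta(pts))
    assert summ.loc[0, "contributing_groups_gt5pct"] == 1


def test_border_distances():
    # two unit squares 10 km apart edge-to-edge
    q = [[0.95, 0.05]] * 4 + [[0.05, 0.95]] * 4
    pts = [(0, 0), (1, 0), (1, 1), (0, 1),
           (11, 0), (12, 0), (12, 1), (11, 1)]
    part, qm = _partition(q)
    geom = build_group_polygons(part, _meta(pts))
    summ = group_summary(qm, part, geom, _meta(pts))
    assert summ.nearest_border_km.tolist() == pytest.approx([10.0, 10.0])
    # overlapping hulls -> 0
    pts2 = [(0, 0), (2, 0), (2, 2), (0, 2), (1, 1), (3, 1), (3, 3), (1, 3)]
    geom2 = build_group_polygons(part, _meta(pts2))
    summ2 = group_summary(qm, part, geom2, _meta(pts2))
    assert summ2.nearest_border_km.tolist() == pytest.approx([0.0, 0.0])


def test_degenerate_cluster_flagged():
    q = [[0.95, 0.05]] * 2 + [[0.05, 0.95]] * 4
    pts = [(0, 0), (1, 0), (10, 10), (11, 10), (11, 11), (10, 11)]
    with pytest.warns(UserWarning, match="degenerate"):
        geom = build_group_polygons(_partition(q)[0], _meta(pts))
    assert geom.shape(0).degenerate
    assert np.isnan(geom.shape(0).area_total)


def test_track_overlap_counts():
    q = [[0.95, 0.05]] * 4 + [[0.05, 0.95]] * 4
    pts = [(0, 0), (10, 0), (10, 10), (0, 10),
           (100, 0), (110, 0), (110, 10), (100, 10)]
    part, _ = _partition(q)
    geom = build_group_polygons(part, _meta(pts))
    base = dt.date(2010, 1, 1)

    def track(aid, coords):
        return TrackRecord(aid, [(base + dt.timedelta(days=i), x, y)
                                 for i, (x, y) in enumerate(coords)])

    inside = track("in", [(1, 1), (8, 2), (5, 8), (2, 5)])
    spanning = track("span", [(1, 1), (9, 9), (105, 5), (108, 8)])
    out = track("out", [(500, 500), (501, 500), (500, 501)])
    df = track_mcp_overlap([inside, spanning, out], geom)
    assert df.loc["in", "n_groups_overlapped"] == 1
    assert df.loc["span", "n_groups_overlapped"] == 2
    assert df.loc["out", "n_groups_overlapped"] == 0


def test_degenerate_track_falls_back_to_points():
    q = [[0.95, 0.05]] * 4 + [[0.05, 0.95]] * 4
    pts = [(0, 0), (10, 0), (10, 10), (0, 10),
           (100, 0), (110, 0), (110, 10), (100, 10)]
    part, _ = _partition(q)
    geom = build_group_polygons(part, _meta(pts))
    base = dt.date(2010, 1, 1)
    tr = TrackRecord("two", [(base, 1.0, 1.0), (base + dt.timedelta(days=1), 2.0, 2.0)])
    df = track_mcp_overlap([tr], geom)
    assert bool(df.loc["two", "degenerate"])
    assert df.loc["two", "n_groups_overlapped"] == 1


@given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                min_size=3, max_size=12, unique=True))
def test_hull_monotonicity(points):
    pts = np.array(points)
    hull = MultiPoint(points).convex_hull
    # adding an interior point never changes the hull
    centroid = tuple(pts.mean(axis=0))
    hull2 = MultiPoint(points + [centroid]).convex_hull
    assert hull2.equals_exact(hull, 1e-9) or hull2.area == pytest.approx(hull.area)
    # adding an exterior point never shrinks it
    hull3 = MultiPoint(points + [(200.0, 200.0)]).convex_hull
    assert hull3.area >= hull.area - 1e-9


@given(seed=st.integers(0, 1000))
def test_raising_adjacency_never_increases_blocks(seed):
    rng = np.random.default_rng(seed)
    xy = rng.random((12, 2)) * 100
    counts = [len(_single_linkage_blocks(xy, c)) for c in (5, 20, 50, 200)]
    assert counts == sorted(counts, reverse=True)
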