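"""Pairwise distances, contact detection and bout extraction."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

import polycontact as pc
from polycontact.contacts import BOUT_COLUMNS


def segment_distance(p1, p2, q1, q2):
    """Minimum distance between two segments (clamped-projection oracle)."""

    def point_seg(p, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
        return float(np.linalg.norm(p - (a + t * ab)))

    def segs_intersect(a, b, c, d):
        def orient(p, q, r):
            v = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
            return 0 if abs(v) < 1e-15 else (1 if v > 0 else -1)

        o1, o2 = orient(a, b, c), orient(a, b, d)
        o3, o4 = orient(c, d, a), orient(c, d, b)
        return o1 != o2 and o3 != o4

    if segs_intersect(p1, p2, q1, q2):
        return 0.0
    return min(
        point_seg(p1, q1, q2),
        point_seg(p2, q1, q2),
        point_seg(q1, p1, p2),
        point_seg(q2, p1, p2),
    )


def brute_force_polygon_distance(verts_a, verts_b):
    """O(n^2) edge-pair distance oracle with containment handling."""
    from matplotlib.path import Path

    best = np.inf
    na, nb = len(verts_a), len(verts_b)
    for i in range(na):
        for j in range(nb):
            best = min(
                best,
                segment_distance(
                    verts_a[i], verts_a[(i + 1) % na], verts_b[j], verts_b[(j + 1) % nb]
                ),
            )
    # full containment: no edges intersect but one centroid lies inside
    if best > 0 and (
        Path(verts_a).contains_point(verts_b[0]) or Path(verts_b).contains_point(verts_a[0])
    ):
        return 0.0
    return best


def random_convex_polygon(rng, center, scale):
    pts = rng.normal(center, scale, size=(8, 2))
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    return pts[hull.vertices]


class TestGeometryDistance:
    def test_shared_edge_is_zero(self):
        a = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        b = Polygon([(1, 0), (2, 0), (2, 1), (1, 1)])
        assert pc.geometry_distance(a, b) == 0.0

    def test_unit_gap(self):
        a = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        b = Polygon([(2, 0), (3, 0), (3, 1), (2, 1)])
        assert pc.geometry_distance(a, b) == 1.0

    def test_contained_point_is_zero(self):
        square = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert pc.geometry_distance(Point(0.5, 0.5), square) == 0.0
        assert pc.geometry_distance((0.5, 0.5), square) == 0.0

    def test_invalid_ring_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(pc.GeometryError):
            pc.geometry_distance(bowtie, Point(0, 0))

    def test_500_random_convex_pairs_match_brute_force(self, rng):
        for k in range(500):
            a = random_convex_polygon(rng, rng.uniform(0, 10, 2), 1.5)
            b = random_convex_polygon(rng, rng.uniform(0, 10, 2), 1.5)
            got = pc.geometry_distance(Polygon(a), Polygon(b))
            expected = brute_force_polygon_distance(a, b)
            assert got == pytest.approx(expected, abs=1e-9), f"pair {k}"


def series_from(entries):
    """entries: (id, time, part, shapely geometry)."""
    return pd.DataFrame(entries, columns=["id", "time", "part", "geometry"]).assign(
        heading=0.0
    )


def unit_square_at(x, y):
    return Polygon([(x, y), (x + 1, y), (x + 1, y + 1), (x, y + 1)])


class TestPairwiseDistances:
    def test_two_individuals_one_part_one_record(self):
        series = series_from(
            [("a", 0, "body", unit_square_at(0, 0)), ("b", 0, "body", unit_square_at(2, 0))]
        )
        dist = pc.pairwise_distances(series, [("body", "body")])
        assert len(dist) == 1
        assert dist["distance"].iloc[0] == 1.0

    def test_three_individuals_head_head_three_records(self):
        series = series_from(
            [(i, 0, "head", unit_square_at(k * 3, 0)) for k, i in enumerate("abc")]
        )
        dist = pc.pairwise_distances(series, [("head", "head")])
        assert len(dist) == 3  # C(3, 2)

    def test_asymmetric_pairing_emits_both_orderings(self):
        series = series_from(
            [
                ("a", 0, "head", unit_square_at(0, 0)),
                ("a", 0, "posterior", unit_square_at(-2, 0)),
                ("b", 0, "head", unit_square_at(5, 0)),
                ("b", 0, "posterior", unit_square_at(3, 0)),
            ]
        )
        dist = pc.pairwise_distances(series, [("head", "posterior")])
        assert len(dist) == 2
        combos = {(r.id_a, r.part_a, r.id_b, r.part_b) for r in dist.itertuples()}
        assert combos == {("a", "head", "b", "posterior"), ("b", "head", "a", "posterior")}

    def test_self_pairs_excluded(self):
        series = series_from(
            [
                ("a", 0, "head", unit_square_at(0, 0)),
                ("a", 0, "posterior", unit_square_at(-2, 0)),
            ]
        )
        dist = pc.pairwise_distances(series, [("head", "posterior")])
        assert dist.empty

    def test_missing_part_raises(self):
        series = series_from([("a", 0, "head", unit_square_at(0, 0))])
        with pytest.raises(pc.ConfigurationError):
            pc.pairwise_distances(series, [("head", "tail")])

    def test_missing_fix_yields_no_record(self):
        series = series_from(
            [
                ("a", 0, "body", unit_square_at(0, 0)),
                ("b", 0, "body", unit_square_at(2, 0)),
                ("a", 1, "body", unit_square_at(0, 0)),
            ]
        )
        dist = pc.pairwise_distances(series, [("body", "body")])
        assert list(dist["time"]) == [0]

    def test_symmetry_of_undirected_distances(self, rng):
        series = series_from(
            [
                ("a", 0, "body", unit_square_at(*rng.uniform(0, 5, 2))),
                ("b", 0, "body", unit_square_at(*rng.uniform(0, 5, 2))),
            ]
        )
        d_ab = pc.pairwise_distances(series, [("body", "body")])["distance"].iloc[0]
        swapped = series.copy()
        swapped["id"] = ["b", "a"]
        d_ba = pc.pairwise_distances(swapped, [("body", "body")])["distance"].iloc[0]
        assert d_ab == pytest.approx(d_ba)

    def test_directed_point_in_polygon_not_symmetrized(self):
        triangle = Polygon([(0, 0), (10, 10), (-10, 10)])
        series = pd.concat(
            [
                series_from([("a", 0, "visual", triangle)]),
                pd.DataFrame(
                    {"id": ["b"], "time": [0], "part": ["point"], "geometry": [Point(0, 5)], "heading": [0.0]}
                ),
                pd.DataFrame(
                    {"id": ["a"], "time": [0], "part": ["point"], "geometry": [Point(0, 0)], "heading": [0.0]}
                ),
                series_from([("b", 0, "visual", Polygon([(0, 5), (10, 15), (-10, 15)]))]),
            ],
            ignore_index=True,
        )
        dist = pc.pairwise_distances(series, [("visual", "point")], directed=True)
        d = {(r.id_a, r.id_b): r.distance for r in dist.itertuples()}
        assert d[("a", "b")] == 0.0  # b sits inside a's field
        assert d[("b", "a")] > 0.0  # a is behind b's apex


class TestDetectContacts:
    @pytest.mark.parametrize(
        "distance,spth,expected",
        [(0.0, 0.0, True), (0.56, 0.56, True), (0.561, 0.56, False)],
    )
    def test_inclusive_threshold(self, distance, spth, expected):
        dist = pd.DataFrame(
            [(0, "a", "body", "b", "body", False, distance)],
            columns=["time", "id_a", "part_a", "id_b", "part_b", "directed", "distance"],
        )
        flags = pc.detect_contacts(dist, spth)
        assert flags["contact"].iloc[0] == expected

    def test_contact_set_monotone_in_spth(self, rng):
        distances = rng.uniform(0, 2, 200)
        dist = pd.DataFrame(
            {
                "time": np.arange(200),
                "id_a": "a",
                "part_a": "body",
                "id_b": "b",
                "part_b": "body",
                "directed": False,
                "distance": distances,
            }
        )
        small = set(pc.detect_contacts(dist, 0.3).query("contact")["time"])
        large = set(pc.detect_contacts(dist, 0.9).query("contact")["time"])
        assert small <= large


def flags_from_bits(bits, interval=10):
    return pd.DataFrame(
        {
            "time": np.arange(len(bits)) * interval,
            "id_a": "a",
            "part_a": "body",
            "id_b": "b",
            "part_b": "body",
            "directed": False,
            "contact": [bool(b) for b in bits],
        }
    )


class TestExtractBouts:
    def grid(self, n, interval=10):
        return pc.GridSpec(interval=interval, start=0, end=n * interval)

    def test_runs_split_on_gap(self):
        bouts = pc.extract_bouts(flags_from_bits([1, 1, 1, 0, 1]), self.grid(5))
        assert list(bouts["n_timesteps"]) == [3, 1]
        assert list(bouts["start_time"]) == [0, 40]
        assert list(bouts["end_time"]) == [20, 40]

    def test_all_zero_flags_empty(self):
        bouts = pc.extract_bouts(flags_from_bits([0, 0, 0]), self.grid(3))
        assert bouts.empty
        assert list(bouts.columns) == BOUT_COLUMNS

    def test_max_gap_merges_runs(self):
        bouts = pc.extract_bouts(flags_from_bits([1, 1, 0, 1, 1]), self.grid(5), max_gap=1)
        assert len(bouts) == 1
        assert bouts["n_timesteps"].iloc[0] == 4  # in-contact steps only

    def test_missing_timestep_breaks_bout(self):
        flags = flags_from_bits([1, 1, 1, 1])
        flags = flags[flags["time"] != 20]  # fix missing entirely at t=20
        bouts = pc.extract_bouts(flags, self.grid(4))
        assert list(bouts["n_timesteps"]) == [2, 1]

    def test_total_steps_conserved_over_random_strings(self, rng):
        for _ in range(25):
            bits = rng.integers(0, 2, size=50)
            bouts = pc.extract_bouts(flags_from_bits(bits), self.grid(50))
            assert bouts["n_timesteps"].sum() == bits.sum()
            # maximality: bout boundaries touch non-contact or series edges
            for row in bouts.itertuples():
                k0, k1 = row.start_time // 10, row.end_time // 10
                assert k0 == 0 or bits[k0 - 1] == 0
                assert k1 == 49 or bits[k1 + 1] == 0
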