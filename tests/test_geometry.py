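import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combmetrics.geometry import (
    ArcSet, GeometryError, PitPairStimulus, PitStimulus, VStimulus,
    WallSegment, angular_divergence, bisection_orientation,
    common_tangent_orientation, nearest_wall_corners,
    proximity_ratio, rim_wall_overlap, splay_angle,
    undirected_orientation, wall_between_centres,
)

# ---------------------------------------------------------------------------
# independent oracle: dense angular sampling of the overlap operator
# ---------------------------------------------------------------------------

def sampled_overlap_deg(pit, walls, tol_mm, step_deg=0.1):
    """Rim overlap measured by brute-force sampling of the gauge circle."""
    angles = np.arange(0.0, 360.0, step_deg)
    pts = np.asarray(pit.centre) + pit.radius * np.column_stack(
        [np.cos(np.radians(angles)), np.sin(np.radians(angles))])
    hit = np.zeros(len(angles), dtype=bool)
    for w in walls:
        a, b = np.asarray(w.p1), np.asarray(w.p2)
        d = b - a
        t = np.clip((pts - a) @ d / (d @ d), 0.0, 1.0)
        proj = a + t[:, None] * d
        hit |= np.hypot(*(proj - pts).T) <= tol_mm
    return hit.mean() * 360.0


def random_rigid_motion(rng):
    th = rng.uniform(0, 2 * math.pi)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    t = rng.uniform(-50, 50, 2)
    return lambda p: tuple(R @ np.asarray(p) + t)


class TestOrientations:
    @pytest.mark.parametrize(
        "p1,p2,expect",
        [((0, 0), (1, 0), 0.0), ((0, 0), (0, 1), 90.0), ((0, 0), (1, 1), 45.0)],
    )
    def test_examples(self, p1, p2, expect):
        assert undirected_orientation(WallSegment(p1, p2)) == pytest.approx(expect)

    def test_undirectedness(self):
        a = undirected_orientation(WallSegment((0, 0), (-1, 1)))
        b = undirected_orientation(WallSegment((0, 0), (1, -1)))
        assert a == pytest.approx(b)

    def test_zero_length_rejected(self):
        with pytest.raises(GeometryError):
            WallSegment((1, 1), (1, 1))

    @pytest.mark.parametrize(
        "a,b,expect", [(10, 10, 0.0), (0, 90, 90.0), (10, 170, 20.0), (179, 1, 2.0)]
    )
    def test_divergence_examples(self, a, b, expect):
        assert angular_divergence(a, b) == pytest.approx(expect)

    @given(a=st.floats(-720, 720), b=st.floats(-720, 720),
           k=st.integers(-3, 3))
    @settings(derandomize=True, max_examples=200)
    def test_divergence_properties(self, a, b, k):
        d = angular_divergence(a, b)
        assert 0.0 <= d <= 90.0
        assert d == pytest.approx(angular_divergence(b, a), abs=1e-9)
        assert d == pytest.approx(angular_divergence(a + 180 * k, b), abs=1e-9)


class TestTangentAndBisection:
    def test_tangent_examples(self):
        assert common_tangent_orientation(PitPairStimulus((0, 0), (2, 0))) == pytest.approx(90.0)
        assert common_tangent_orientation(PitPairStimulus((0, 0), (0, 2))) == pytest.approx(0.0)

    def test_tangent_orthogonal_to_centre_line(self, rng):
        for _ in range(200):
            a, b = rng.uniform(-10, 10, 2), rng.uniform(-10, 10, 2)
            if np.hypot(*(a - b)) < 1e-6:
                continue
            pair = PitPairStimulus(tuple(a), tuple(b))
            tangent = math.radians(common_tangent_orientation(pair))
            tdir = np.array([math.cos(tangent), math.sin(tangent)])
            cdir = (b - a) / np.hypot(*(b - a))
            assert abs(float(tdir @ cdir)) < 1e-9

    def test_coincident_centres_rejected(self):
        with pytest.raises(GeometryError):
            PitPairStimulus((1, 1), (1, 1))

    def test_bisector_right_angle_v(self):
        v = VStimulus((1, 0), (0, 0), (0, 1))
        assert bisection_orientation(v) == pytest.approx(45.0)

    def test_bisector_mirror_symmetric_v_is_vertical(self):
        # arms mirror-symmetric about the vertical axis through the apex
        v = VStimulus((-1, 1), (0, 0), (1, 1))
        assert bisection_orientation(v) == pytest.approx(90.0)

    def test_bisector_equiangular_to_arms(self, rng):
        for _ in range(200):
            apex = rng.uniform(-10, 10, 2)
            a1 = rng.uniform(0, 360)
            splay = rng.uniform(5, 175)
            e1 = apex + rng.uniform(1, 5) * np.array(
                [math.cos(math.radians(a1)), math.sin(math.radians(a1))])
            e2 = apex + rng.uniform(1, 5) * np.array(
                [math.cos(math.radians(a1 + splay)), math.sin(math.radians(a1 + splay))])
            v = VStimulus(tuple(e1), tuple(apex), tuple(e2))
            bis = bisection_orientation(v)
            arm_a = math.degrees(math.atan2(e1[1] - apex[1], e1[0] - apex[0]))
            arm_b = math.degrees(math.atan2(e2[1] - apex[1], e2[0] - apex[0]))
            da = angular_divergence(bis, arm_a)
            db = angular_divergence(bis, arm_b)
            assert da == pytest.approx(db, abs=1e-9)

    def test_splay_right_angle(self):
        assert splay_angle(VStimulus((1, 0), (0, 0), (0, 1))) == pytest.approx(90.0)

    def test_splay_straight_arms_degenerate(self):
        with pytest.raises(GeometryError):
            splay_angle(VStimulus((-1, 0), (0, 0), (1, 0)))
        with pytest.raises(GeometryError):
            bisection_orientation(VStimulus((-1, 0), (0, 0), (1, 0)))

    def test_splay_law_of_cosines(self, rng):
        for _ in range(100):
            apex = rng.uniform(-5, 5, 2)
            e1 = apex + rng.uniform(-5, 5, 2)
            e2 = apex + rng.uniform(-5, 5, 2)
            if min(np.hypot(*(e1 - apex)), np.hypot(*(e2 - apex))) < 0.1:
                continue
            v = VStimulus(tuple(e1), tuple(apex), tuple(e2))
            la = np.hypot(*(e1 - apex))
            lb = np.hypot(*(e2 - apex))
            lc = np.hypot(*(e1 - e2))
            expect = math.degrees(
                math.acos(np.clip((la**2 + lb**2 - lc**2) / (2 * la * lb), -1, 1)))
            if expect < 1e-6 or expect > 180 - 1e-6:
                continue
            assert splay_angle(v) == pytest.approx(expect, abs=1e-9)


class TestRimOverlap:
    def test_empty_wall_list(self):
        arcs = rim_wall_overlap(PitStimulus((0, 0)), [], tol_mm=0.35)
        assert arcs.total_degrees == 0.0

    def test_long_wall_through_centre_gives_antipodal_arcs(self):
        pit = PitStimulus((0, 0))
        wall = WallSegment((-100, 0), (100, 0))
        tol = 0.1
        arcs = rim_wall_overlap(pit, [wall], tol_mm=tol)
        # two antipodal arcs, each of half-width asin(tol / r); the one
        # straddling 0 deg is stored split at the seam
        width = 2 * math.degrees(math.asin(tol / pit.radius))
        assert arcs.total_degrees == pytest.approx(2 * width, abs=0.01)
        assert arcs.contains(0.0) and arcs.contains(180.0)
        assert not arcs.contains(90.0) and not arcs.contains(270.0)

    def test_wall_tangent_at_exact_tolerance_distance(self):
        pit = PitStimulus((0, 0))
        tol = 0.35
        wall = WallSegment((-10, pit.radius + tol), (10, pit.radius + tol))
        arcs = rim_wall_overlap(pit, [wall], tol_mm=tol)
        assert arcs.total_degrees < 0.5

    def test_against_sampling_oracle_random_configurations(self, rng):
        pit = PitStimulus((0, 0))
        for _ in range(100):
            walls = [
                WallSegment(tuple(rng.uniform(-4, 4, 2)), tuple(rng.uniform(-4, 4, 2)))
                for _ in range(rng.integers(1, 4))
            ]
            tol = rng.uniform(0.1, 0.8)
            analytic = rim_wall_overlap(pit, walls, tol_mm=tol).total_degrees
            sampled = sampled_overlap_deg(pit, walls, tol)
            assert abs(analytic - sampled) < 0.5

    def test_chord_inside_band(self, rng):
        # a chord at distance < tol from the rim where it crosses
        pit = PitStimulus((0, 0))
        wall = WallSegment((-pit.radius, 0.05), (pit.radius, 0.05))
        analytic = rim_wall_overlap(pit, [wall], tol_mm=0.4).total_degrees
        sampled = sampled_overlap_deg(pit, [wall], 0.4)
        assert abs(analytic - sampled) < 0.5

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(GeometryError):
            rim_wall_overlap(PitStimulus((0, 0)), [], tol_mm=0.0)


class TestArcSet:
    def test_union_merges_overlaps(self):
        a = ArcSet([(10, 50), (40, 80)])
        assert a.intervals == [(10.0, 80.0)]

    def test_wraparound_normalization(self):
        a = ArcSet([(350, 370)])
        assert a.total_degrees == pytest.approx(20.0)
        assert a.contains(355) and a.contains(5) and not a.contains(20)

    def test_intersection(self):
        a = ArcSet([(0, 90)])
        b = ArcSet([(45, 180)])
        assert a.intersection(b).intervals == [(45.0, 90.0)]

    @given(st.lists(st.tuples(st.floats(-360, 720), st.floats(0, 400)),
                    max_size=6))
    @settings(derandomize=True, max_examples=200)
    def test_invariants(self, raw):
        arcs = ArcSet([(s, s + w) for s, w in raw])
        assert 0.0 <= arcs.total_degrees <= 360.0 + 1e-9
        ivs = arcs.intervals
        assert all(0.0 <= s < e <= 360.0 for s, e in ivs)
        assert all(ivs[i][1] < ivs[i + 1][0] + 1e-9 for i in range(len(ivs) - 1))


class TestExclusionRule:
    def test_wall_between_centres(self):
        pair = PitPairStimulus((0, 0), (6, 0))
        assert wall_between_centres(pair, WallSegment((3, -5), (3, 5)))

    def test_wall_beyond_a_centre(self):
        pair = PitPairStimulus((0, 0), (6, 0))
        assert not wall_between_centres(pair, WallSegment((8, -5), (8, 5)))

    def test_parallel_non_intersecting_excluded(self):
        pair = PitPairStimulus((0, 0), (6, 0))
        assert not wall_between_centres(pair, WallSegment((0, 2), (6, 2)))

    def test_offset_along_own_axis_still_counts(self):
        # the infinite line, not the finite segment, is what matters
        pair = PitPairStimulus((0, 0), (6, 0))
        assert wall_between_centres(pair, WallSegment((3, 5), (3, 10)))

    def test_against_parametric_oracle(self, rng):
        for _ in range(1000):
            a, b = rng.uniform(-5, 5, 2), rng.uniform(-5, 5, 2)
            w1, w2 = rng.uniform(-5, 5, 2), rng.uniform(-5, 5, 2)
            if np.hypot(*(a - b)) < 1e-3 or np.hypot(*(w1 - w2)) < 1e-3:
                continue
            pair = PitPairStimulus(tuple(a), tuple(b))
            wall = WallSegment(tuple(w1), tuple(w2))
            # oracle: solve a + t(b - a) = w1 + s(w2 - w1) for t, s
            M = np.column_stack([b - a, -(w2 - w1)])
            if abs(np.linalg.det(M)) < 1e-12:
                expect = False
            else:
                t, _ = np.linalg.solve(M, w1 - a)
                expect = bool(0.0 < t < 1.0)
            assert wall_between_centres(pair, wall) == expect


class TestCornersAndProximity:
    def test_nearest_corner_example(self):
        walls = [WallSegment((1, 0), (5, 0)), WallSegment((3, 0), (7, 0))]
        d1, d2, ids = nearest_wall_corners((0, 0), walls)
        assert (d1, d2) == (1.0, 3.0)
        assert ids == (0, 1)

    def test_tie_broken_by_order(self):
        walls = [WallSegment((2, 0), (5, 0)), WallSegment((-2, 0), (-5, 0))]
        d1, d2, ids = nearest_wall_corners((0, 0), walls)
        assert d1 == d2 == 2.0
        assert ids == (0, 1)

    def test_fewer_than_two_walls_rejected(self):
        with pytest.raises(GeometryError):
            nearest_wall_corners((0, 0), [WallSegment((1, 0), (2, 0))])

    def test_against_brute_force_scan(self, rng):
        for _ in range(100):
            apex = rng.uniform(-5, 5, 2)
            walls = [WallSegment(tuple(rng.uniform(-10, 10, 2)),
                                 tuple(rng.uniform(-10, 10, 2)))
                     for _ in range(6)]
            d1, d2, _ = nearest_wall_corners(tuple(apex), walls)
            dists = sorted(
                min(np.hypot(*(np.asarray(w.p1) - apex)),
                    np.hypot(*(np.asarray(w.p2) - apex)))
                for w in walls)
            assert d1 == pytest.approx(dists[0]) and d2 == pytest.approx(dists[1])

    @pytest.mark.parametrize("d1,d2,expect", [(1, 1, 0.5), (1, 3, 0.25), (2, 6, 0.25)])
    def test_proximity_examples(self, d1, d2, expect):
        assert proximity_ratio(d1, d2) == pytest.approx(expect)

    def test_proximity_monotone_in_d1_at_fixed_sum(self):
        total = 8.0
        vals = [proximity_ratio(d1, total - d1) for d1 in (1.0, 2.0, 3.0, 4.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_ordering_violation_rejected(self):
        with pytest.raises(GeometryError):
            proximity_ratio(3.0, 1.0)

    def test_zero_d1_boundary(self):
        assert proximity_ratio(0.0, 5.0) == 0.0


class TestRigidMotionInvariance:
    def test_all_metrics_invariant(self, rng):
        for _ in range(20):
            move = random_rigid_motion(rng)
            pit = PitStimulus((1.0, 2.0))
            pair = PitPairStimulus((0.0, 0.0), (5.5, 1.0))
            v = VStimulus((3.0, 1.0), (1.0, 1.0), (1.5, 4.0))
            walls = [WallSegment(tuple(rng.uniform(-4, 6, 2)),
                                 tuple(rng.uniform(-4, 6, 2))) for _ in range(4)]
            m_pit = PitStimulus(move(pit.centre))
            m_pair = PitPairStimulus(move(pair.centre_a), move(pair.centre_b))
            m_v = VStimulus(move(v.end_a), move(v.apex), move(v.end_b))
            m_walls = [WallSegment(move(w.p1), move(w.p2)) for w in walls]

            assert rim_wall_overlap(pit, walls, 0.5).total_degrees == pytest.approx(
                rim_wall_overlap(m_pit, m_walls, 0.5).total_degrees, abs=1e-6)
            assert angular_divergence(
                undirected_orientation(walls[0]), common_tangent_orientation(pair)
            ) == pytest.approx(angular_divergence(
                undirected_orientation(m_walls[0]),
                common_tangent_orientation(m_pair)), abs=1e-6)
            assert angular_divergence(
                undirected_orientation(walls[0]), bisection_orientation(v)
            ) == pytest.approx(angular_divergence(
                undirected_orientation(m_walls[0]), bisection_orientation(m_v)),
                abs=1e-6)
            assert splay_angle(v) == pytest.approx(splay_angle(m_v), abs=1e-6)
            d1, d2, _ = nearest_wall_corners(v.apex, walls)
            md1, md2, _ = nearest_wall_corners(m_v.apex, m_walls)
            assert proximity_ratio(d1, d2) == pytest.approx(
                proximity_ratio(md1, md2), abs=1e-6)
            assert wall_between_centres(pair, walls[0]) == wall_between_centres(
                m_pair, m_walls[0])
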