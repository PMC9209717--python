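"""Stage 1: closed polygonal principal-curve fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsegmod.ccps import (
    CCPSConfig,
    ClosedPolyline,
    DegenerateVarianceError,
    NormalizationParams,
    PointSet,
    data_radius,
    denormalize,
    filter_vertices,
    fit_ccps,
    init_square,
    insert_vertex,
    optimize_vertices,
    project_points,
    stop_whole_loop,
    to_vertex_sequence,
    zscore_normalize,
)


def square_cloud(n_per_side=10, scale=100.0, offset=50.0):
    s = np.linspace(0, 1, n_per_side, endpoint=False)
    pts = np.concatenate(
        [
            np.column_stack([s, np.zeros_like(s)]),
            np.column_stack([np.ones_like(s), s]),
            np.column_stack([1 - s, np.ones_like(s)]),
            np.column_stack([np.zeros_like(s), 1 - s]),
        ]
    )
    return PointSet(pts * scale + offset)


class TestZScore:
    def test_corners_example(self):
        pts = PointSet(np.array([[0.0, 0.0], [2, 0], [0, 2], [2, 2]] * 2))
        out, params = zscore_normalize(pts)
        assert np.allclose(sorted(map(tuple, out.xy)), sorted(map(tuple, [(-1, -1), (1, -1), (-1, 1), (1, 1)] * 2)))
        assert params.mu_x == params.mu_y == 1.0
        assert params.sigma_x == params.sigma_y == 1.0

    def test_output_standardized_and_roundtrip(self, rng):
        pts = PointSet(rng.normal([30, 70], [5, 11], size=(200, 2)))
        out, params = zscore_normalize(pts)
        assert np.all(np.abs(out.xy.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(out.xy.std(axis=0) - 1) < 1e-9)
        back = denormalize(out.xy, params)
        assert np.all(np.abs(back - pts.xy) < 1e-9)

    def test_already_standard_is_fixed_point(self, rng):
        raw = rng.normal(size=(50, 2))
        raw = (raw - raw.mean(axis=0)) / raw.std(axis=0)
        out, _ = zscore_normalize(PointSet(raw))
        assert np.all(np.abs(out.xy - raw) < 1e-9)

    def test_degenerate_variance(self):
        pts = PointSet(np.tile([3.0, 4.0], (10, 1)))
        with pytest.raises(DegenerateVarianceError):
            zscore_normalize(pts)

    def test_denormalize_examples(self):
        p = NormalizationParams(1, 1, 1, 1)
        assert np.allclose(denormalize(np.array([0.0, 0.0]), p), [1, 1])
        p2 = NormalizationParams(5, 5, 2, 3)
        assert np.allclose(denormalize(np.array([1.0, -1.0]), p2), [7, 2])

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 8"):
            zscore_normalize(PointSet(np.eye(2)))


class TestInitSquare:
    def test_printed_vertices(self):
        sq = init_square()
        assert sq.n_vertices == 4
        assert np.allclose(
            sq.vertices, [[0.1, 0.1], [-0.1, 0.1], [-0.1, -0.1], [0.1, -0.1]]
        )

    def test_closed_ccw_and_symmetric(self):
        sq = init_square()
        assert sq.is_ccw()
        flipped = -sq.vertices
        assert {tuple(v) for v in flipped} == {tuple(v) for v in sq.vertices}


class TestProjection:
    def test_vertex_coincidence_and_square_edge(self):
        sq = init_square()
        pts = PointSet(np.array([[0.1, 0.1], [0.0, 0.0]]))
        proj = project_points(pts, sq)
        assert proj.kind[0] == 0 and proj.sqdist[0] == 0.0
        assert proj.sqdist[1] == pytest.approx(0.01)

    def test_brute_force_oracle(self, rng):
        # oracle: independent scan over vertices and densely sampled segments
        for _ in range(10):
            m = rng.integers(3, 10)
            verts = rng.normal(size=(m, 2))
            try:
                curve = ClosedPolyline(verts)
            except ValueError:
                continue
            pts = PointSet(rng.normal(size=(30, 2)))
            proj = project_points(pts, curve)
            for i, p in enumerate(pts.xy):
                best = np.inf
                for j in range(m):
                    best = min(best, np.sum((p - verts[j]) ** 2))
                    a, b = verts[j], verts[(j + 1) % m]
                    for u in np.linspace(0, 1, 2001):
                        best = min(best, float(np.sum((p - (a + u * (b - a))) ** 2)))
                assert proj.sqdist[i] == pytest.approx(best, abs=1e-5)

    def test_delta_n_is_mean(self, rng):
        curve = init_square()
        pts = PointSet(rng.normal(size=(20, 2)))
        proj = project_points(pts, curve)
        assert proj.delta_n == pytest.approx(proj.sqdist.mean())
        assert proj.vertex_counts.sum() + proj.segment_counts.sum() == 20


class TestDataRadius:
    def test_examples(self):
        theta = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        circ = PointSet(np.column_stack([np.cos(theta), np.sin(theta)]))
        assert data_radius(circ) == pytest.approx(1.0)
        assert data_radius(PointSet(np.array([[5.0, 5.0]]))) == 0.0
        assert data_radius(PointSet(np.array([[0.0, 0.0], [2.0, 0.0]]))) == pytest.approx(1.0)


class TestOptimizeVertices:
    def test_never_worse_and_cluster_attraction(self, rng):
        centers = np.array([[0, 2.0], [-2, -1.0], [2, -1.0]])
        pts = PointSet(
            np.concatenate([rng.normal(c, 0.05, size=(15, 2)) for c in centers])
        )
        tri = ClosedPolyline(np.array([[0, 1.0], [-1, -0.5], [1, -0.5]]))
        cfg = CCPSConfig()
        before = project_points(pts, tri).delta_n
        out = optimize_vertices(tri, pts, cfg)
        after = project_points(pts, out).delta_n
        assert after <= before + 1e-12
        # each optimized vertex close to a distinct cluster center
        d = np.linalg.norm(out.vertices[:, None, :] - centers[None], axis=2)
        assert np.all(d.min(axis=1) < 0.3)

    def test_local_optimum_fixed_point(self, rng):
        pts = PointSet(rng.normal(size=(40, 2)))
        cfg = CCPSConfig()
        once = optimize_vertices(init_square(), pts, cfg)
        twice = optimize_vertices(once, pts, cfg)
        t1 = project_points(pts, once).total
        t2 = project_points(pts, twice).total
        assert t1 - t2 < cfg.delta_s


class TestInsertVertex:
    def test_splits_worst_segment(self):
        sq = init_square()
        # misfit concentrated near the bottom edge (segment 2: (-0.1,-0.1)->(0.1,-0.1))
        pts = PointSet(
            np.array([[0.0, -0.3], [0.02, -0.3], [-0.02, -0.3], [0.0, 0.09],
                      [0.05, 0.0], [-0.05, 0.0], [0.0, -0.05], [0.01, 0.0]])
        )
        proj = project_points(pts, sq)
        out = insert_vertex(sq, proj)
        assert out.n_vertices == 5
        # inserted between the bottom edge endpoints, at the centroid of its points
        new = [v for v in map(tuple, out.vertices) if tuple(v) not in map(tuple, sq.vertices)]
        assert len(new) == 1
        # the new vertex is the centroid of the points on the split segment
        on_bottom = (proj.kind == 1) & (proj.index == 2)
        assert np.allclose(new[0], pts.xy[on_bottom].mean(axis=0))
        assert new[0][1] < -0.1  # split happened on the misfit (bottom) side
        # original vertices all retained
        for v in sq.vertices:
            assert any(np.allclose(v, w) for w in out.vertices)

    def test_no_splittable_segment(self):
        from hsegmod.ccps import NoSplittableSegmentError

        sq = init_square()
        pts = PointSet(np.array([[0.1, 0.1], [-0.1, 0.1], [-0.1, -0.1]]))
        proj = project_points(pts, sq)
        with pytest.raises(NoSplittableSegmentError):
            insert_vertex(sq, proj)


class TestFilterVertices:
    def _curve_with_outlier(self):
        theta = 2 * np.pi * np.arange(8) / 8
        verts = np.column_stack([np.cos(theta), np.sin(theta)])
        verts[3] *= 2.5  # vertex far outside the data radius
        return ClosedPolyline(verts)

    def test_removes_far_vertex(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 100)
        pts = PointSet(np.column_stack([np.cos(theta), np.sin(theta)]))
        curve = self._curve_with_outlier()
        proj = project_points(pts, curve)
        r = data_radius(pts)
        out, warnings = filter_vertices(curve, proj, r, CCPSConfig(), pts.centroid())
        assert out.n_vertices == 7
        assert not any(np.linalg.norm(v) > 1.5 for v in out.vertices)
        assert any("radius" in w[1] for w in warnings)

    def test_removes_starved_vertex(self):
        # 4 clusters of 6 points at the square corners, plus a spurious
        # vertex whose neighborhood captures almost nothing
        corners = np.array([[1, 1.0], [-1, 1], [-1, -1], [1, -1]])
        pts = PointSet(np.concatenate(
            [np.tile(c, (6, 1)) + 0.001 * np.arange(6)[:, None] * c for c in corners]
        ))
        verts = np.vstack([corners, [[1.0, 0.0]]])  # extra vertex mid-edge
        order = [0, 4, 3, 2, 1]  # keep polygon simple: (1,1),(1,0),(1,-1),(-1,-1),(-1,1)
        curve = ClosedPolyline(verts[order])
        proj = project_points(pts, curve)
        out, warnings = filter_vertices(curve, proj, data_radius(pts), CCPSConfig(), pts.centroid())
        assert out.n_vertices == 4
        assert not any(np.allclose(v, [1.0, 0.0]) for v in out.vertices)

    def test_healthy_curve_unchanged(self, rng):
        theta = 2 * np.pi * np.arange(6) / 6
        verts = 0.9 * np.column_stack([np.cos(theta), np.sin(theta)])
        curve = ClosedPolyline(verts)
        t2 = rng.uniform(0, 2 * np.pi, 200)
        pts = PointSet(np.column_stack([np.cos(t2), np.sin(t2)]))
        proj = project_points(pts, curve)
        out, warnings = filter_vertices(curve, proj, data_radius(pts), CCPSConfig(), pts.centroid())
        assert out.n_vertices == 6
        assert warnings == []


class TestStopRule:
    def test_threshold_example(self):
        cfg = CCPSConfig()
        # beta * 1000^(1/3) * 0.04^(-1/2) * 1.5 = 0.3*10*5*1.5 = 22.5
        assert stop_whole_loop(23, 1000, 0.04, 1.5, cfg) is True
        assert stop_whole_loop(22, 1000, 0.04, 1.5, cfg) is False

    def test_perfect_fit_stops(self):
        assert stop_whole_loop(4, 100, 0.0, 1.0, CCPSConfig()) is True

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            stop_whole_loop(4, 100, -1.0, 1.0, CCPSConfig())


class TestFitCCPS:
    def test_square_recovery(self):
        from hsegmod.ccps import _element_distances

        pts = square_cloud()
        curve, seq, trace = fit_ccps(pts)
        _, params = zscore_normalize(pts)
        corners_px = np.array([[150, 150.0], [50, 150], [50, 50], [150, 50]])
        sq_poly = ClosedPolyline((corners_px - params.mu) / params.sigma)

        # symmetric Hausdorff between the fitted polyline and the data
        # square, both densely sampled in normalized space
        def densify(verts):
            out = []
            for j in range(len(verts)):
                a, b = verts[j], verts[(j + 1) % len(verts)]
                for u in np.linspace(0, 1, 400, endpoint=False):
                    out.append(a + u * (b - a))
            return np.array(out)

        d1 = np.sqrt(_element_distances(densify(curve.vertices), sq_poly).min(axis=1)).max()
        d2 = np.sqrt(_element_distances(densify(sq_poly.vertices), curve).min(axis=1)).max()
        assert max(d1, d2) < 1e-2

    def test_noisy_circle_properties(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 200)
        radius = 100.0
        xy = radius * np.column_stack([np.cos(theta), np.sin(theta)])
        xy += rng.normal(0, 0.02 * radius, size=xy.shape)
        curve, seq, trace = fit_ccps(PointSet(xy + 150))
        history = trace.delta_n_history()
        assert history[-1] < history[0]
        # vertex count consistent with the segment-count bound at termination
        normalized, _ = zscore_normalize(PointSet(xy + 150))
        r = data_radius(normalized)
        cfg = CCPSConfig()
        bound = cfg.beta_stop * 200 ** (1 / 3) * history[-1] ** -0.5 * r
        assert curve.n_segments <= bound or trace.stop_reason == "segment-count bound"

    def test_delta_n_non_increasing_within_tolerance(self, bundle):
        seeds, _, _ = bundle
        _, _, trace = fit_ccps(seeds)
        h = trace.delta_n_history()
        assert np.all(np.diff(h) <= CCPSConfig().delta_s + 1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_ccps(PointSet(np.random.default_rng(0).normal(size=(5, 2))))

    def test_deterministic(self, bundle):
        seeds, _, _ = bundle
        _, seq1, _ = fit_ccps(seeds)
        _, seq2, _ = fit_ccps(seeds)
        assert np.array_equal(seq1.t, seq2.t)
        assert np.array_equal(seq1.xy, seq2.xy)


class TestVertexSequence:
    def test_unit_square_parameterization(self):
        poly = ClosedPolyline(np.array([[1, 1.0], [-1, 1], [-1, -1], [1, -1]]))
        seq = to_vertex_sequence(poly, NormalizationParams(0, 0, 1, 1))
        assert np.allclose(seq.t, [0, 0.25, 0.5, 0.75, 1.0])
        assert np.allclose(seq.xy[0], seq.xy[-1])
        assert np.allclose(seq.xy[0], [1, 1])  # max x, tie broken by max y

    def test_storage_order_invariance(self):
        verts = np.array([[1, 1.0], [-1, 1], [-1, -1], [1, -1]])
        p = NormalizationParams(0, 0, 1, 1)
        seq_a = to_vertex_sequence(ClosedPolyline(verts), p)
        seq_b = to_vertex_sequence(ClosedPolyline(np.roll(verts, 2, axis=0)), p)
        seq_c = to_vertex_sequence(ClosedPolyline(verts[::-1]), p)  # reversed (cw)
        for other in (seq_b, seq_c):
            assert np.allclose(seq_a.xy, other.xy)
            assert np.allclose(seq_a.t, other.t)

    @given(m=st.integers(min_value=3, max_value=40), seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_t_invariants(self, m, seed):
        rng = np.random.default_rng(seed)
        theta = np.sort(rng.uniform(0, 2 * np.pi, m))
        if np.any(np.diff(theta) < 1e-6):
            return
        verts = np.column_stack([np.cos(theta), np.sin(theta)]) * rng.uniform(0.5, 2)
        seq = to_vertex_sequence(ClosedPolyline(verts), NormalizationParams(0, 0, 1, 1))
        assert seq.t[0] == 0.0 and seq.t[-1] == 1.0
        assert np.all(np.diff(seq.t) > 0)
        assert np.allclose(seq.xy[0], seq.xy[-1])
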