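import itertools

import numpy as np
import pytest

from facepulse.mesh import (N_LANDMARKS, canonical_template,
                            default_region_polygons, default_topology)
from facepulse.roi import (PolygonError, TopologyError, chrominance_filter,
                           filter_anatomical, rasterize_triangle, rgb_to_yuv,
                           select_rois, tessellate)
from facepulse.video import CanonicalReference, FrameSequence


def _canon(points):
    pts = np.zeros((N_LANDMARKS, 2))
    pts[:len(points)] = points
    return CanonicalReference(points=pts)


class TestTessellate:
    def test_toy_centroid(self):
        canon = _canon([(0, 0), (2, 0), (0, 2)])
        tris = tessellate(canon, topology=np.array([[0, 1, 2]]))
        np.testing.assert_allclose(tris[0].centroid, [2 / 3, 2 / 3])

    def test_full_topology_centroids_in_bbox(self):
        canon = CanonicalReference(points=canonical_template())
        tris = tessellate(canon)
        for tri in tris:
            v = canon.points[list(tri.vertex_indices)]
            assert (v[:, 0].min() <= tri.centroid[0] <= v[:, 0].max())
            assert (v[:, 1].min() <= tri.centroid[1] <= v[:, 1].max())

    def test_duplicate_vertex_raises(self):
        canon = _canon([(0, 0), (1, 0), (0, 1)])
        with pytest.raises(TopologyError):
            tessellate(canon, topology=np.array([[0, 0, 1]]))

    def test_out_of_range_index_raises(self):
        canon = _canon([(0, 0)])
        with pytest.raises(TopologyError):
            tessellate(canon, topology=np.array([[0, 1, N_LANDMARKS]]))


class TestAnatomicalFilter:
    def _square_setup(self):
        # landmarks 0-3 form a unit square polygon; triangles use 4-6
        pts = [(0, 0), (10, 0), (10, 10), (0, 10),
               (1, 1), (3, 1), (1, 3),  # triangle inside
               (20, 20), (22, 20), (20, 22)]  # triangle outside
        canon = _canon(pts)
        polys = {"forehead": [0, 1, 2, 3]}
        return canon, polys

    def test_inside_retained_outside_discarded(self):
        canon, polys = self._square_setup()
        tris = tessellate(canon, topology=np.array([[4, 5, 6], [7, 8, 9]]))
        kept = filter_anatomical(tris, canon, polys)
        assert len(kept) == 1
        assert kept[0].vertex_indices == (4, 5, 6)
        assert kept[0].region == "forehead"

    def test_edge_centroid_counts_as_inside(self):
        # centroid exactly on x=0 edge of the square; half-plane oracle:
        # 0 <= x <= 10 and 0 <= y <= 10 holds with equality on x
        canon = _canon([(0, 0), (10, 0), (10, 10), (0, 10),
                        (0, 2), (0, 6), (0, 4)])
        canon.points[4:7] = [(-1, 2), (1, 2), (0, 8)]  # centroid (0, 4)
        tris = tessellate(canon, topology=np.array([[4, 5, 6]]))
        kept = filter_anatomical(tris, canon, {"forehead": [0, 1, 2, 3]})
        assert len(kept) == 1

    def test_self_intersecting_polygon_raises(self):
        canon = _canon([(0, 0), (10, 10), (10, 0), (0, 10), (1, 1), (2, 1), (1, 2)])
        tris = tessellate(canon, topology=np.array([[4, 5, 6]]))
        with pytest.raises(PolygonError):
            filter_anatomical(tris, canon, {"forehead": [0, 1, 2, 3]})


class TestRasterize:
    @staticmethod
    def _bruteforce(verts, h, w):
        out = set()
        (x0, y0), (x1, y1), (x2, y2) = verts
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        for y in range(h):
            for x in range(w):
                d0 = (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0)
                d1 = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
                d2 = (x0 - x2) * (y - y2) - (y0 - y2) * (x - x2)
                if area < 0:
                    d0, d1, d2 = -d0, -d1, -d2
                if d0 >= 0 and d1 >= 0 and d2 >= 0:
                    out.add((y, x))
        return out

    @pytest.mark.parametrize("verts", [
        [(0, 0), (4, 0), (0, 4)],
        [(1.5, 0.2), (6.7, 2.9), (2.1, 7.3)],
        [(0, 0), (7, 1), (3, 6)],
    ])
    def test_matches_bruteforce(self, verts):
        rr, cc = rasterize_triangle(np.array(verts, dtype=float), 8, 8)
        assert set(zip(rr, cc)) == self._bruteforce(verts, 8, 8)

    def test_zero_area_empty(self):
        rr, cc = rasterize_triangle(np.array([(1, 1), (3, 3), (5, 5)]), 8, 8)
        assert rr.size == 0

    def test_offframe_clipped(self):
        rr, cc = rasterize_triangle(np.array([(-5, -5), (5, -5), (-5, 5)]), 8, 8)
        inside = self._bruteforce([(-5, -5), (5, -5), (-5, 5)], 8, 8)
        assert set(zip(rr, cc)) == inside
        assert all(0 <= r < 8 and 0 <= c < 8 for r, c in zip(rr, cc))


def _uv_video(canon, tri_uv, topology, h=40, w=40, n_frames=4):
    """Paint each triangle with an RGB whose chrominance equals tri_uv."""
    from facepulse.roi import _YUV

    frames = np.full((n_frames, h, w, 3), 0.5)
    inv = np.linalg.inv(_YUV)
    for row, (u, v) in zip(topology, tri_uv):
        rgb = inv @ np.array([128.0, u, v]) / 255.0
        rr, cc = rasterize_triangle(canon.points[row], h, w)
        frames[:, rr, cc] = rgb
    return FrameSequence(frames=np.clip(frames, 0, 1), fps=20.0)


class TestChrominanceFilter:
    def _setup(self, uv_list):
        # lay out len(uv_list) disjoint triangles on a 40x40 grid
        pts = []
        topo = []
        for i in range(len(uv_list)):
            x0 = 2 + (i % 4) * 9
            y0 = 2 + (i // 4) * 9
            pts += [(x0, y0), (x0 + 7, y0), (x0, y0 + 7)]
            topo.append([3 * i, 3 * i + 1, 3 * i + 2])
        canon = _canon(pts)
        topo = np.array(topo)
        tris = tessellate(canon, topology=topo)
        video = _uv_video(canon, uv_list, topo)
        return canon, tris, video

    @staticmethod
    def _exhaustive_2means(points):
        """Best 2-partition by within-cluster sum of squares (<= 8 points)."""
        pts = np.asarray(points)
        best, best_cost = None, np.inf
        n = len(pts)
        for mask in range(1, 2 ** n - 1):
            lab = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
            cost = sum(((pts[g] - pts[g].mean(axis=0)) ** 2).sum()
                       for g in (lab, ~lab) if g.any())
            if cost < best_cost:
                best, best_cost = lab, cost
        return best

    def test_two_blobs_keep_reference_side(self):
        uv = [(30, 45), (31, 44), (29, 46), (-60, -60), (-59, -61)]
        canon, tris, video = self._setup(uv)
        kept = chrominance_filter(tris, video, seed=0, landmarks=canon.points)
        kept_ids = {t.vertex_indices for t in kept}
        assert kept_ids == {tris[i].vertex_indices for i in range(3)}
        # the retained set matches the exhaustive 2-means partition
        lab = self._exhaustive_2means(uv)
        ref_side = lab if lab[0] else ~lab
        assert {i for i in range(5) if ref_side[i]} == {0, 1, 2}

    def test_identical_uv_all_retained(self):
        uv = [(10.0, 20.0)] * 4
        canon, tris, video = self._setup(uv)
        kept = chrominance_filter(tris, video, seed=0, landmarks=canon.points)
        assert len(kept) == 4

    def test_single_candidate_skips_clustering(self):
        uv = [(10.0, 20.0)]
        canon, tris, video = self._setup(uv)
        kept = chrominance_filter(tris, video, seed=0, landmarks=canon.points)
        assert len(kept) == 1

    def test_deterministic_given_seed(self, rng):
        uv = [tuple(x) for x in rng.uniform(-40, 60, (8, 2))]
        canon, tris, video = self._setup(uv)
        k1 = chrominance_filter([t for t in tris], video, seed=7,
                                landmarks=canon.points)
        k2 = chrominance_filter([t for t in tris], video, seed=7,
                                landmarks=canon.points)
        assert [t.vertex_indices for t in k1] == [t.vertex_indices for t in k2]


class TestSceneShadowAgreement:
    def test_shadowed_triangles_discarded(self, small_scene):
        """The chrominance filter must reject the generator's shadowed
        cheek triangles and keep the lit ones."""
        from facepulse.video import (SyntheticLandmarkProvider,
                                     build_canonical_reference,
                                     detect_landmarks)

        _, video, truth = small_scene
        track = detect_landmarks(video, SyntheticLandmarkProvider(truth.landmarks))
        canon = build_canonical_reference(track)
        topo = default_topology()
        tris = tessellate(canon)
        cand = filter_anatomical(tris, canon)
        kept = chrominance_filter(cand, video, seed=0, landmarks=canon.points)
        kept_rows = {topo.tolist().index(sorted(t.vertex_indices))
                     for t in kept}
        shadowed = set(truth.shadowed_triangles.tolist())
        assert not (kept_rows & shadowed), "shadowed triangles survived"
        # the anatomical candidates that are NOT shadowed mostly survive
        cand_rows = {topo.tolist().index(sorted(t.vertex_indices))
                     for t in cand}
        lit = cand_rows - shadowed
        assert len(kept_rows) >= 0.8 * len(lit)

    def test_retained_is_subset_of_candidates(self, small_scene):
        from facepulse.video import (SyntheticLandmarkProvider,
                                     build_canonical_reference,
                                     detect_landmarks)

        _, video, truth = small_scene
        track = detect_landmarks(video, SyntheticLandmarkProvider(truth.landmarks))
        canon = build_canonical_reference(track)
        cand = filter_anatomical(tessellate(canon), canon)
        cand_ids = {t.vertex_indices for t in cand}
        kept = select_rois(canon, video, seed=0)
        assert {t.vertex_indices for t in kept} <= cand_ids


class TestYUV:
    def test_grey_has_zero_chrominance(self):
        yuv = rgb_to_yuv(np.array([128.0, 128.0, 128.0]))
        assert yuv[0] == pytest.approx(128.0)
        assert abs(yuv[1]) < 1e-9 and abs(yuv[2]) < 1e-9

    def test_warm_skin_positive_uv(self):
        yuv = rgb_to_yuv(np.array([190.0, 140.0, 115.0]))
        assert yuv[1] > 0 and yuv[2] > 0
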