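"""Facial ROI tessellation, anatomical filtering and chrominance filtering.

The canonical face is tessellated into small triangles; triangles whose
centroids fall inside the forehead or cheek polygons become candidates, and a
2-means clustering in chrominance (U, V) space keeps only the well-lit ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from sklearn.cluster import KMeans

from .mesh import N_LANDMARKS, default_region_polygons, default_topology
from .video import CanonicalReference, FrameSequence

log = logging.getLogger(__name__)

__all__ = [
    "TriangleROI",
    "tessellate",
    "filter_anatomical",
    "chrominance_filter",
    "rasterize_triangle",
    "rgb_to_yuv",
    "select_rois",
]


class TopologyError(ValueError):
    pass


class PolygonError(ValueError):
    pass


@dataclass
class TriangleROI:
    """A landmark-index triangle with canonical-space metadata."""

    vertex_indices: tuple[int, int, int]
    centroid: np.ndarray  # canonical (x, y)
    region: str | None = None  # forehead / left_cheek / right_cheek
    mean_rgb: np.ndarray | None = None  # temporal-mean RGB, 0-255 scale
    mean_uv: np.ndarray | None = None
    retained: bool = True


def tessellate(canonical: CanonicalReference,
               topology: np.ndarray | None = None) -> list[TriangleROI]:
    """One TriangleROI per topology row, centroid in canonical space."""
    if topology is None:
        topology = default_topology()
    topology = np.asarray(topology, dtype=int)
    pts = canonical.points
    tris: list[TriangleROI] = []
    for row in topology:
        i, j, k = (int(v) for v in row)
        if len({i, j, k}) != 3:
            raise TopologyError(f"duplicate vertex indices in triangle {row}")
        if not all(0 <= v < len(pts) for v in (i, j, k)):
            raise TopologyError(f"vertex index out of range in triangle {row}")
        centroid = pts[[i, j, k]].mean(axis=0)
        tris.append(TriangleROI(vertex_indices=(i, j, k), centroid=centroid))
    return tris


def filter_anatomical(triangles: list[TriangleROI],
                      canonical: CanonicalReference,
                      polygons: dict[str, list[int]] | None = None
                      ) -> list[TriangleROI]:
    """Keep triangles whose centroid lies inside any region polygon.

    Polygons are ordered landmark-index loops in canonical space; a centroid
    exactly on an edge counts as inside.
    """
    if polygons is None:
        polygons = default_region_polygons()
    shapes: dict[str, Polygon] = {}
    for name, loop in polygons.items():
        poly = Polygon(canonical.points[np.asarray(loop, dtype=int)])
        if not poly.is_valid or not poly.is_simple:
            raise PolygonError(f"region polygon {name!r} is self-intersecting")
        shapes[name] = poly
    kept: list[TriangleROI] = []
    for tri in triangles:
        pt = Point(tri.centroid)
        for name, poly in shapes.items():
            if poly.covers(pt):  # boundary counts as inside
                tri.region = name
                kept.append(tri)
                break
    return kept


def rasterize_triangle(vertices: np.ndarray, height: int, width: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Pixels whose centers lie inside the triangle (inclusive edges).

    Returns ``(rows, cols)`` index arrays; empty for degenerate triangles.
    Off-frame parts are clipped.
    """
    v = np.asarray(vertices, dtype=float)
    (x0, y0), (x1, y1), (x2, y2) = v
    area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
    if area == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    xmin = max(int(np.floor(v[:, 0].min())), 0)
    xmax = min(int(np.ceil(v[:, 0].max())), width - 1)
    ymin = max(int(np.floor(v[:, 1].min())), 0)
    ymax = min(int(np.ceil(v[:, 1].max())), height - 1)
    if xmin > xmax or ymin > ymax:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    xs = np.arange(xmin, xmax + 1)
    ys = np.arange(ymin, ymax + 1)
    X, Y = np.meshgrid(xs, ys)
    # barycentric signs, inclusive of edges
    d0 = (x1 - x0) * (Y - y0) - (y1 - y0) * (X - x0)
    d1 = (x2 - x1) * (Y - y1) - (y2 - y1) * (X - x1)
    d2 = (x0 - x2) * (Y - y2) - (y0 - y2) * (X - x2)
    if area < 0:
        d0, d1, d2 = -d0, -d1, -d2
    inside = (d0 >= 0) & (d1 >= 0) & (d2 >= 0)
    return Y[inside].astype(int), X[inside].astype(int)


_YUV = np.array([
    [0.299, 0.587, 0.114],
    [0.492 * 0.299, 0.492 * 0.587, -0.492 * (1 - 0.114)],
    [0.877 * (1 - 0.299), -0.877 * 0.587, -0.877 * 0.114],
])


def rgb_to_yuv(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma with zero-centered chrominance, axes oriented for skin.

    Y is the BT.601 luma; the chrominance pair is U = 0.492 (Y - B),
    V = 0.877 (R - Y).  The U axis is deliberately oriented so that warm,
    well-lit skin (R > G > B) has positive U and V on the 0-255 scale,
    landing near the default well-lit reference point (U, V) = (30, 45);
    shadowed or bluish regions fall toward the origin and beyond.  The exact
    convention is not critical because clustering adapts per scene; only the
    orientation relative to the reference point matters.
    """
    return np.asarray(rgb, dtype=float) @ _YUV.T


def chrominance_filter(candidates: list[TriangleROI], raw_video: FrameSequence,
                       reference_uv: tuple[float, float] = (30.0, 45.0),
                       seed: int = 0,
                       landmarks: np.ndarray | None = None,
                       ) -> list[TriangleROI]:
    """2-means in (U, V) on per-triangle temporal-mean color; keep the
    cluster nearest the well-lit-skin reference chrominance.

    ``landmarks`` gives the per-frame vertex positions (defaults to the
    canonical positions implied by each triangle's stored centroid geometry
    is not available here, so the caller passes the layout used to rasterize;
    for a stabilized video this is the canonical layout).
    """
    if landmarks is None:
        raise ValueError("landmarks (478, 2) layout required for rasterization")
    H, W = raw_video.shape
    mean_frame = raw_video.frames.mean(axis=0)  # temporal mean image
    feats = []
    usable = []
    for tri in candidates:
        rr, cc = rasterize_triangle(landmarks[list(tri.vertex_indices)], H, W)
        if rr.size == 0:
            tri.retained = False
            continue
        rgb = mean_frame[rr, cc].mean(axis=0) * 255.0
        tri.mean_rgb = rgb
        yuv = rgb_to_yuv(rgb)
        tri.mean_uv = yuv[1:]
        feats.append(yuv[1:])
        usable.append(tri)
    if len(usable) < 2:
        log.warning("fewer than 2 candidate triangles; skipping clustering")
        for tri in usable:
            tri.retained = True
        return usable
    X = np.asarray(feats)
    if np.allclose(X, X[0]):
        for tri in usable:
            tri.retained = True
        return usable
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(X)
    ref = np.asarray(reference_uv, dtype=float)
    d = np.linalg.norm(km.cluster_centers_ - ref, axis=1)
    if np.isclose(d[0], d[1]):  # tie: fail open, keep everything
        winners = {0, 1}
    else:
        winners = {int(np.argmin(d))}
    out = []
    for tri, lab in zip(usable, km.labels_):
        tri.retained = int(lab) in winners
        if tri.retained:
            out.append(tri)
    return out


def spatial_order(triangles: list[TriangleROI]) -> list[TriangleROI]:
    """Order traces spatially: forehead, then left cheek, then right cheek,
    each left-to-right (then top-to-bottom) by canonical centroid."""
    rank = {"forehead": 0, "left_cheek": 1, "right_cheek": 2, None: 3}
    return sorted(triangles, key=lambda t: (rank.get(t.region, 3),
                                            round(float(t.centroid[0]), 3),
                                            float(t.centroid[1])))


def select_rois(canonical: CanonicalReference, raw_video: FrameSequence,
                reference_uv=(30.0, 45.0), seed: int = 0,
                topology=None, polygons=None,
                chrominance: bool = True) -> list[TriangleROI]:
    """Full ROI selection: tessellate, anatomical filter, chrominance filter,
    spatial ordering.  ``chrominance=False`` skips the illumination filter
    (ablation switch)."""
    tris = tessellate(canonical, topology)
    cand = filter_anatomical(tris, canonical, polygons)
    if chrominance:
        kept = chrominance_filter(cand, raw_video, reference_uv, seed,
                                  landmarks=canonical.points)
    else:
        kept = cand
    return spatial_order(kept)
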