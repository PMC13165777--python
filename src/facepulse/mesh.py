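"""Synthetic 478-point canonical face layout, triangulation and region polygons.

The pipeline works on a dense face mesh with the same cardinality as the
478-point face-mesh topology used by common landmark detectors.  Because no
detector model ships with this package, the canonical layout used for testing
and for the synthetic scene generator is itself synthetic: 478 points arranged
on concentric elliptical rings inside a face-shaped oval, triangulated with a
Delaunay triangulation.  Forehead and cheek region polygons are index loops
over this layout.  All of it is deterministic and generated in code, so no
third-party mesh asset is required.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.spatial import Delaunay

N_LANDMARKS = 478

# vertical half-axis of the face oval relative to horizontal (faces are tall)
_ASPECT = 1.3


@functools.lru_cache(maxsize=1)
def canonical_template() -> np.ndarray:
    """Return the (478, 2) synthetic canonical layout in normalized coords.

    Points satisfy ``u**2 + (v/1.3)**2 <= 1`` with ``u`` rightward and ``v``
    downward (image convention); the face centre is the origin.
    """
    pts: list[tuple[float, float]] = []
    n_boundary = 36
    ang = 2 * np.pi * np.arange(n_boundary) / n_boundary
    for a in ang:
        pts.append((np.cos(a), _ASPECT * np.sin(a)))
    # interior rings, counts shrinking with radius
    n_rings = 13
    radii = 1.0 - (np.arange(1, n_rings + 1)) / (n_rings + 1)
    counts = np.maximum(6, np.round(n_boundary * radii)).astype(int)
    # trim/extend so the total is exactly N_LANDMARKS (one centre point)
    budget = N_LANDMARKS - n_boundary - 1
    while counts.sum() > budget:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < budget:
        counts[np.argmin(counts)] += 1
    for r, c, k in zip(radii, counts, range(n_rings)):
        offs = np.pi * k / n_rings  # stagger rings so triangles are well shaped
        a = 2 * np.pi * np.arange(c) / c + offs
        for aa in a:
            pts.append((r * np.cos(aa), _ASPECT * r * np.sin(aa)))
    pts.append((0.0, 0.0))
    out = np.asarray(pts, dtype=float)
    assert out.shape == (N_LANDMARKS, 2)
    return out


@functools.lru_cache(maxsize=1)
def default_topology() -> np.ndarray:
    """Delaunay triangle-index list (ntri, 3) over the canonical template."""
    tri = Delaunay(canonical_template())
    return np.sort(tri.simplices, axis=1).astype(int)


def _nearest_index(points: np.ndarray, target: tuple[float, float]) -> int:
    d = np.hypot(points[:, 0] - target[0], points[:, 1] - target[1])
    return int(np.argmin(d))


def _snap_loop(corners: list[tuple[float, float]]) -> list[int]:
    """Snap a parametric loop to nearest distinct landmark indices."""
    pts = canonical_template()
    loop: list[int] = []
    for c in corners:
        i = _nearest_index(pts, c)
        if i not in loop:
            loop.append(i)
    return loop


@functools.lru_cache(maxsize=1)
def default_region_polygons() -> dict[str, list[int]]:
    """Index loops for the forehead and cheek regions on the canonical layout.

    The loops are rectangles in normalized face coordinates snapped to the
    nearest landmarks; they deliberately exclude the eye/mouth band
    (``v`` in roughly [-0.45, 0.15]).
    """

    def rect(x0, x1, y0, y1, n=4):
        xs = np.linspace(x0, x1, n)
        ys = np.linspace(y0, y1, n)
        loop = [(x, y0) for x in xs]
        loop += [(x1, y) for y in ys[1:]]
        loop += [(x, y1) for x in xs[::-1][1:]]
        loop += [(x0, y) for y in ys[::-1][1:-1]]
        return loop

    return {
        "forehead": _snap_loop(rect(-0.62, 0.62, -1.12, -0.52)),
        "left_cheek": _snap_loop(rect(-0.80, -0.22, 0.12, 0.72)),
        "right_cheek": _snap_loop(rect(0.22, 0.80, 0.12, 0.72)),
    }


def template_to_frame(template: np.ndarray, center: tuple[float, float],
                      semi_axes: tuple[float, float]) -> np.ndarray:
    """Map normalized template coordinates to pixel coordinates.

    ``semi_axes = (ax, ay)`` are the face half-width and half-height in
    pixels; the template's vertical extent (±1.3) is scaled to ±ay.
    """
    cx, cy = center
    ax, ay = semi_axes
    out = np.empty_like(template)
    out[:, 0] = cx + template[:, 0] * ax
    out[:, 1] = cy + template[:, 1] * (ay / _ASPECT)
    return out
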