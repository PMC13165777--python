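"""Two-stage geometric stabilization into the canonical face frame.

Stage 1 estimates a 4-DOF similarity (translation, in-plane rotation,
isotropic scale) from the current landmarks to the canonical reference,
smooths each parameter with an adaptive exponential moving average, and warps
the frame.  Stage 2 removes residual horizontal translation by tracking two
facial-boundary points with subpixel patch registration and subtracting their
mean horizontal displacement from the canonical x-positions.  Jitter metrics
quantify the residual motion over high-motion segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import SimilarityTransform

from .video import CanonicalReference, FrameSequence, LandmarkTrack

log = logging.getLogger(__name__)

__all__ = [
    "AffineParams",
    "SmootherState",
    "JitterReport",
    "estimate_similarity",
    "smooth_params",
    "ParamSmoother",
    "warp_to_canonical",
    "translational_refine",
    "jitter_metrics",
    "stabilize_video",
]


class DegeneratePointsError(ValueError):
    """All landmarks coincide; no transform can be estimated."""


@dataclass
class AffineParams:
    """4-DOF similarity: p' = s*R(theta)*p + (tx, ty)."""

    tx: float
    ty: float
    theta: float
    s: float
    residual: float = 0.0

    def matrix(self) -> np.ndarray:
        """2x3 matrix [s*R | t] reconstructed exactly from the parameters."""
        c, si = np.cos(self.theta), np.sin(self.theta)
        return np.array(
            [[self.s * c, -self.s * si, self.tx],
             [self.s * si, self.s * c, self.ty]]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineParams":
        """Decompose a 4-DOF matrix; exact inverse of :meth:`matrix`."""
        s = float(np.hypot(m[0, 0], m[1, 0]))
        theta = float(np.arctan2(m[1, 0], m[0, 0]))
        return cls(tx=float(m[0, 2]), ty=float(m[1, 2]), theta=theta, s=s)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        m = self.matrix()
        return pts @ m[:, :2].T + m[:, 2]


def estimate_similarity(landmarks: np.ndarray,
                        canonical: np.ndarray | CanonicalReference) -> AffineParams:
    """Least-squares similarity mapping current landmarks onto the canonical
    layout (Umeyama / Procrustes)."""
    if isinstance(canonical, CanonicalReference):
        canonical = canonical.points
    src = np.asarray(landmarks, dtype=float)
    dst = np.asarray(canonical, dtype=float)
    if not (np.isfinite(src).all() and np.isfinite(dst).all()):
        raise ValueError("landmarks must be finite")
    if np.allclose(src, src[0]):
        raise DegeneratePointsError("all landmarks coincident")
    if hasattr(SimilarityTransform, "from_estimate"):
        tf = SimilarityTransform.from_estimate(src, dst)
        if not tf:
            raise DegeneratePointsError("similarity estimation failed")
    else:  # older scikit-image
        tf = SimilarityTransform()
        if not tf.estimate(src, dst):
            raise DegeneratePointsError("similarity estimation failed")
    p = AffineParams.from_matrix(np.asarray(tf.params)[:2])
    p.residual = float(np.sqrt(np.mean(np.sum((p.apply(src) - dst) ** 2, axis=1))))
    return p


@dataclass
class SmootherState:
    """Adaptive-EMA state for the four similarity parameters."""

    alpha_slow: float = 0.05
    alpha_fast: float = 0.8
    theta_threshold: float = 0.05  # radians
    alpha_step: float = 0.15
    smoothed: AffineParams | None = None
    alpha: float = 0.05
    correction_active: bool = False


class ParamSmoother:
    """Per-parameter EMA with a rotation-triggered correction phase.

    The baseline factor alpha_slow filters detector jitter; when the raw
    rotation deviates from the smoothed rotation by more than
    ``theta_threshold`` radians, alpha ramps toward alpha_fast so the filter
    converges on the new head pose, then resets to alpha_slow once the
    rotational error subsides.
    """

    def __init__(self, state: SmootherState | None = None):
        self.state = state or SmootherState()
        self.state.alpha = self.state.alpha_slow

    def update(self, p: AffineParams) -> AffineParams:
        st = self.state
        if st.smoothed is None:
            st.smoothed = AffineParams(p.tx, p.ty, p.theta, p.s)
            return st.smoothed
        err = abs(p.theta - st.smoothed.theta)
        if err > st.theta_threshold:
            st.correction_active = True
            st.alpha = min(st.alpha_fast, st.alpha + st.alpha_step)
        else:
            st.correction_active = False
            st.alpha = st.alpha_slow
        a = st.alpha
        prev = st.smoothed
        st.smoothed = AffineParams(
            tx=(1 - a) * prev.tx + a * p.tx,
            ty=(1 - a) * prev.ty + a * p.ty,
            theta=(1 - a) * prev.theta + a * p.theta,
            s=(1 - a) * prev.s + a * p.s,
        )
        return st.smoothed


def smooth_params(params, state: SmootherState | None = None):
    """Smooth a stream of AffineParams; returns the list of smoothed params."""
    sm = ParamSmoother(state)
    return [sm.update(p) for p in params]


def warp_to_canonical(frame: np.ndarray, params: AffineParams) -> np.ndarray:
    """Resample a frame under the similarity so content lands at its
    canonical position.  Bilinear interpolation, replicated borders."""
    if params.s <= 0 or not np.isfinite(params.matrix()).all():
        raise ValueError("invalid transform parameters")
    m = params.matrix()
    A = m[:, :2]
    t = m[:, 2]
    Ainv = np.linalg.inv(A)
    # ndimage uses (row, col) = (y, x); convert the x/y convention
    P = np.array([[0, 1], [1, 0]], dtype=float)
    mat = P @ Ainv @ P
    off = P @ (-Ainv @ t)
    if frame.ndim == 2:
        return ndimage.affine_transform(frame, mat, offset=off, order=1,
                                        mode="nearest")
    out = np.empty_like(frame)
    for c in range(frame.shape[2]):
        out[..., c] = ndimage.affine_transform(frame[..., c], mat, offset=off,
                                               order=1, mode="nearest")
    return out


def _luma(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        return frame @ np.array([0.299, 0.587, 0.114])
    return frame


def _sample_patch(img: np.ndarray, cx: float, cy: float, half: int
                  ) -> np.ndarray | None:
    """Bilinear patch sample centred at a subpixel location."""
    h, w = img.shape
    if not (half + 1 <= cx < w - half - 2 and half + 1 <= cy < h - half - 2):
        return None
    ys = cy + np.arange(-half, half + 1)
    xs = cx + np.arange(-half, half + 1)
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(img, [Y.ravel(), X.ravel()], order=1
                                   ).reshape(Y.shape)


def _track_point(prev: np.ndarray, cur: np.ndarray, pt: np.ndarray,
                 half: int = 10, max_iter: int = 20,
                 tol: float = 0.01) -> np.ndarray | None:
    """Track one point between frames with iterative Lucas-Kanade.

    Solves for the patch translation using spatial gradients of the previous
    frame's patch, iterating the warp until the update drops below ``tol``
    pixels.  Returns None when the point is untrackable (off-frame,
    textureless, or diverging)."""
    x0, y0 = float(pt[0]), float(pt[1])
    p0 = _sample_patch(prev, x0, y0, half)
    if p0 is None or p0.std() < 1e-6:
        return None
    gy, gx = np.gradient(p0)
    G = np.array([[np.sum(gx * gx), np.sum(gx * gy)],
                  [np.sum(gx * gy), np.sum(gy * gy)]])
    if np.linalg.det(G) < 1e-12:
        return None
    Ginv = np.linalg.inv(G)
    dx = dy = 0.0
    for _ in range(max_iter):
        p1 = _sample_patch(cur, x0 + dx, y0 + dy, half)
        if p1 is None:
            return None
        err = p1 - p0
        b = np.array([np.sum(gx * err), np.sum(gy * err)])
        ux, uy = -Ginv @ b
        dx += ux
        dy += uy
        if abs(dx) > 3 * half or abs(dy) > 3 * half:
            return None
        if np.hypot(ux, uy) < tol:
            break
    return np.array([x0 + dx, y0 + dy])


def translational_refine(prev_frame: np.ndarray, cur_frame: np.ndarray,
                         tracked_points: np.ndarray,
                         canonical_x: np.ndarray):
    """Stage 2: horizontal-only correction from two boundary points.

    Tracks each point from the previous to the current stabilized frame,
    computes the mean horizontal displacement relative to the canonical
    x-positions, and shifts the frame to cancel it.

    Returns ``(corrected_frame, tx_correction, new_tracked_points)``.
    """
    prev_l, cur_l = _luma(prev_frame), _luma(cur_frame)
    new_pts = []
    for pt in np.atleast_2d(tracked_points):
        moved = _track_point(prev_l, cur_l, np.asarray(pt, dtype=float))
        new_pts.append(moved)
    ok = [p for p in new_pts if p is not None]
    if not ok:
        log.warning("translational refinement: flow failed on all points")
        return cur_frame, 0.0, np.atleast_2d(tracked_points)
    xs = np.array([p[0] for p in ok])
    cx = np.asarray(canonical_x, dtype=float)[: len(ok)]
    dx = float(np.mean(xs - cx))
    out_pts = np.array([p if p is not None else q
                        for p, q in zip(new_pts, np.atleast_2d(tracked_points))])
    if abs(dx) < 1e-9:
        return cur_frame, 0.0, out_pts
    shift = (0.0, -dx) if cur_frame.ndim == 2 else (0.0, -dx, 0.0)
    corrected = ndimage.shift(cur_frame, shift, order=1, mode="nearest")
    out_pts[:, 0] -= dx
    return corrected, -dx, out_pts


@dataclass
class JitterReport:
    """Residual-motion metrics over high-motion segments."""

    positional_jitter: float  # pixels
    rotational_jitter: float  # radians
    n_high_motion_frames: int
    fallback_whole_trajectory: bool = False


def jitter_metrics(landmark_trajectory: np.ndarray,
                   theta_trajectory: np.ndarray, fps: float) -> JitterReport:
    """Positional and rotational jitter of a cheek landmark.

    High-motion frames are those whose inter-frame landmark speed exceeds the
    mean + 1 SD of all speeds; positional jitter is ``sqrt(var_x + var_y)``
    of the landmark over those frames, rotational jitter the SD of the
    rotation angle over the same frames.
    """
    pts = np.asarray(landmark_trajectory, dtype=float)
    th = np.asarray(theta_trajectory, dtype=float)
    if len(pts) < 3:
        raise ValueError("trajectory too short")
    speed = np.linalg.norm(np.diff(pts, axis=0), axis=1) * fps
    thr = speed.mean() + speed.std()
    high = np.flatnonzero(speed > thr) + 1
    fallback = False
    if high.size < 2:
        high = np.arange(len(pts))
        fallback = True
    sel = pts[high]
    pos = float(np.sqrt(sel[:, 0].var() + sel[:, 1].var()))
    rot = float(th[np.clip(high, 0, len(th) - 1)].std())
    return JitterReport(positional_jitter=pos, rotational_jitter=rot,
                        n_high_motion_frames=int(high.size),
                        fallback_whole_trajectory=fallback)


def stabilize_video(video: FrameSequence, track: LandmarkTrack,
                    canonical: CanonicalReference,
                    state: SmootherState | None = None,
                    boundary_indices: tuple[int, int] | None = None,
                    refine: bool = True):
    """Run both stabilization stages over a video.

    Returns ``(stabilized FrameSequence, stabilized landmark track,
    raw params list, smoothed params list)``.  Undetected frames reuse the
    previous frame's smoothed transform.
    """
    if boundary_indices is None:
        # leftmost and rightmost canonical landmarks = facial boundary
        boundary_indices = (int(np.argmin(canonical.points[:, 0])),
                            int(np.argmax(canonical.points[:, 0])))
    sm = ParamSmoother(state)
    T = video.frame_count
    out = np.empty_like(video.frames)
    stab_pts = np.empty_like(track.points)
    raw_params: list[AffineParams | None] = []
    smoothed_params: list[AffineParams] = []
    prev_smoothed = AffineParams(0.0, 0.0, 0.0, 1.0)
    bidx = np.asarray(boundary_indices, dtype=int)
    canon_b = canonical.points[bidx]
    prev_frame = None
    tracked = None
    for t in range(T):
        if track.detected[t]:
            p = estimate_similarity(track.points[t], canonical)
            p_hat = sm.update(p)
            prev_smoothed = p_hat
        else:
            p = None
            p_hat = prev_smoothed
        raw_params.append(p)
        smoothed_params.append(p_hat)
        frame = warp_to_canonical(video.frames[t], p_hat)
        pts = p_hat.apply(track.points[t])
        if refine:
            if prev_frame is None:
                tracked = pts[bidx].copy()
            else:
                frame, tx, _ = translational_refine(
                    prev_frame, frame, tracked, canon_b[:, 0])
                pts = pts + np.array([tx, 0.0])
                # re-anchor tracking to the landmark positions so flow errors
                # cannot accumulate across the video
                tracked = pts[bidx].copy()
        prev_frame = frame
        out[t] = frame
        stab_pts[t] = pts
    stab = FrameSequence(frames=out, fps=video.fps)
    stab_track = LandmarkTrack(points=stab_pts, detected=track.detected.copy())
    return stab, stab_track, raw_params, smoothed_params
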