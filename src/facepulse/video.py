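"""Video ingestion, landmark providers and the canonical reference face.

Frames are held as float arrays in [0, 1].  Landmark detection is pluggable:
any object with ``detect(frame) -> (478, 2) array or None`` works.  Two
providers ship with the package: a synthetic provider bound to the scene
generator (returns ground-truth landmarks) and an adapter for an external
478-point face-mesh detector, imported lazily so the package works without
the detector installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .mesh import N_LANDMARKS

__all__ = [
    "FrameSequence",
    "LandmarkTrack",
    "CanonicalReference",
    "SyntheticLandmarkProvider",
    "FaceMeshProvider",
    "read_video",
    "write_video",
    "detect_landmarks",
    "build_canonical_reference",
]


class VideoReadError(IOError):
    """Raised when a video file cannot be decoded."""


class TopologyError(ValueError):
    """A landmark provider returned the wrong point count."""


class InsufficientDetectionsError(ValueError):
    """Fewer detected frames than required for the canonical reference."""


@dataclass
class FrameSequence:
    """Ordered color frames with a frame rate.

    frames : (T, H, W, 3) float array with values in [0, 1]
    fps : frames per second
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (T, H, W, 3)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        return self.frame_count / self.fps


@dataclass
class LandmarkTrack:
    """Per-frame 478-point landmarks in pixel coordinates (x right, y down)."""

    points: np.ndarray  # (T, 478, 2)
    detected: np.ndarray  # (T,) bool

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.points.shape[1:] != (N_LANDMARKS, 2):
            raise TopologyError(
                f"expected (T, {N_LANDMARKS}, 2) points, got {self.points.shape}"
            )

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class CanonicalReference:
    """Temporal-mean landmark layout over the first reliably detected frames."""

    points: np.ndarray  # (478, 2)
    n_frames_used: int = 15


class SyntheticLandmarkProvider:
    """Returns ground-truth landmarks recorded by the scene generator."""

    def __init__(self, landmarks: np.ndarray):
        landmarks = np.asarray(landmarks, dtype=float)
        if landmarks.shape[1:] != (N_LANDMARKS, 2):
            raise TopologyError("synthetic landmarks must be (T, 478, 2)")
        self._landmarks = landmarks
        self._t = 0

    def reset(self) -> None:
        self._t = 0

    def detect(self, frame: np.ndarray):
        pts = self._landmarks[self._t]
        self._t += 1
        return pts


class FaceMeshProvider:
    """Adapter for an external 478-point face-mesh detector (e.g. MediaPipe).

    Imported lazily; constructing it without the detector installed raises
    ImportError.  Only the first detected face is used.
    """

    def __init__(self) -> None:
        import mediapipe as mp  # pragma: no cover - optional dependency

        self._mesh = mp.solutions.face_mesh.FaceMesh(
            static_image_mode=False, refine_landmarks=True, max_num_faces=1
        )

    def detect(self, frame: np.ndarray):  # pragma: no cover - optional
        img = (np.clip(frame, 0, 1) * 255).astype(np.uint8)
        res = self._mesh.process(img)
        if not res.multi_face_landmarks:
            return None
        h, w = frame.shape[:2]
        lm = res.multi_face_landmarks[0].landmark
        pts = np.array([[p.x * w, p.y * h] for p in lm], dtype=float)
        if pts.shape[0] != N_LANDMARKS:
            raise TopologyError(f"detector returned {pts.shape[0]} points")
        return pts


def _scale_to_unit(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.dtype == np.uint8:
        return frames.astype(float) / 255.0
    if frames.dtype == np.uint16:
        return frames.astype(float) / 65535.0
    return frames.astype(float)


def read_video(path, target_size: tuple[int, int] | None = (320, 240),
               fps: float | None = None) -> FrameSequence:
    """Read a video file into a FrameSequence.

    Parameters
    ----------
    path : str
        Video file.  Lossless multi-page TIFF and ``.npy``/``.npz`` stacks are
        always supported; AVI/MP4 additionally require an imageio codec
        plugin.
    target_size : (width, height) or None
        Frames are resized to this size (default 320x240); None keeps the
        native size.
    fps : float, optional
        Frame rate override; required for containers that carry none (TIFF,
        npy).  Defaults to 20 fps for those.
    """
    path = str(path)
    meta_fps = None
    try:
        if path.endswith((".tif", ".tiff")):
            import tifffile

            frames = tifffile.imread(path)
        elif path.endswith(".npy"):
            frames = np.load(path)
        elif path.endswith(".npz"):
            with np.load(path) as z:
                frames = z["frames"]
                meta_fps = float(z["fps"]) if "fps" in z else None
        else:
            import imageio.v3 as iio

            frames = iio.imread(path, plugin="pyav" if path.endswith(
                (".mp4", ".avi")) else None)
            try:
                meta = iio.immeta(path)
                meta_fps = float(meta.get("fps")) if meta.get("fps") else None
            except Exception:
                meta_fps = None
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise VideoReadError(f"cannot decode video {path!r}: {exc}") from exc

    frames = np.asarray(frames)
    if frames.ndim == 3:  # grayscale stack -> replicate channels
        frames = np.repeat(frames[..., None], 3, axis=-1)
    if frames.ndim != 4 or frames.shape[0] == 0:
        raise VideoReadError(f"no frames decoded from {path!r}")
    frames = _scale_to_unit(frames)

    if target_size is not None:
        w, h = target_size
        if (frames.shape[2], frames.shape[1]) != (w, h):
            frames = np.stack(
                [_sk_resize(f, (h, w, 3), order=1, anti_aliasing=True,
                            preserve_range=True) for f in frames]
            )
    out_fps = fps if fps is not None else (meta_fps if meta_fps else 20.0)
    return FrameSequence(frames=np.clip(frames, 0.0, 1.0), fps=out_fps)


def write_video(path, video: FrameSequence) -> None:
    """Write a FrameSequence losslessly (TIFF stack or npz with fps)."""
    path = str(path)
    data = (np.clip(video.frames, 0, 1) * 255).round().astype(np.uint8)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, data)
    elif path.endswith(".npz"):
        np.savez_compressed(path, frames=data, fps=video.fps)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data, fps=video.fps)


def detect_landmarks(video: FrameSequence, provider) -> LandmarkTrack:
    """Run the landmark provider over every frame.

    Frames where the provider returns None are flagged ``detected=False`` and
    carry the last detected layout (or zeros before the first detection).
    """
    if hasattr(provider, "reset"):
        provider.reset()
    T = video.frame_count
    pts = np.zeros((T, N_LANDMARKS, 2), dtype=float)
    det = np.zeros(T, dtype=bool)
    last = None
    for t in range(T):
        p = provider.detect(video.frames[t])
        if p is None:
            if last is not None:
                pts[t] = last
            continue
        p = np.asarray(p, dtype=float)
        if p.shape != (N_LANDMARKS, 2):
            raise TopologyError(
                f"provider returned {p.shape[0]} points, expected {N_LANDMARKS}"
            )
        pts[t] = p
        det[t] = True
        last = p
    return LandmarkTrack(points=pts, detected=det)


def build_canonical_reference(track: LandmarkTrack, n: int = 15) -> CanonicalReference:
    """Average the first ``n`` reliably detected frames into a canonical face.

    Scans forward from frame 0, taking the first ``n`` frames with
    ``detected=True``; undetected frames are skipped.
    """
    idx = np.flatnonzero(track.detected)[:n]
    if idx.size < n:
        raise InsufficientDetectionsError(
            f"only {idx.size} detected frames, need {n}"
        )
    mean_pts = track.points[idx].mean(axis=0)
    return CanonicalReference(points=mean_pts, n_frames_used=n)
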