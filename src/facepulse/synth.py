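"""Ground-truthed synthetic scenes, signal mixtures and reference PPG.

The scene generator renders a skin-toned elliptical "face" on a textured
background, injects a weak pulsatile color modulation at a known cardiac
frequency into the skin (green strongest, red half as strong — blood
absorption lowers reflectance), applies rigid motion (slow drift plus
frame-to-frame jitter in translation and rotation), darkens and
chrominance-shifts a shadow region, adds sensor noise, and emits the exact
per-frame landmarks, transforms and a paired 256 Hz reference PPG.  Every
pipeline stage — and the end-to-end HR recovery — is therefore testable with
no dataset download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mesh import (canonical_template, default_region_polygons,
                   default_topology, template_to_frame)
from .roi import rasterize_triangle
from .video import FrameSequence

__all__ = [
    "MotionSpec",
    "ShadowSpec",
    "SceneConfig",
    "SceneTruth",
    "make_scene",
    "make_mixture",
    "make_reference_ppg",
]


@dataclass
class MotionSpec:
    """Rigid head motion: slow sinusoidal drift + white jitter per frame."""

    drift_amplitude: float = 3.0  # px, translation drift
    drift_period: float = 40.0  # s
    jitter_sd: float = 1.5  # px
    rot_drift_amplitude: float = 0.035  # rad, slow rotational drift (~2 deg)
    rot_jitter_sd: float = 0.01  # rad
    step_rotation: float = 0.0  # rad, applied at mid-video if nonzero


@dataclass
class ShadowSpec:
    """A darkened, chrominance-shifted half of one cheek."""

    enabled: bool = True
    side: str = "right"  # which cheek is shadowed
    luminance_factor: float = 0.5
    blue_shift: float = 1.25  # relative boost of B vs R/G inside the shadow


@dataclass
class SceneConfig:
    duration: float = 60.0  # s
    fps: float = 20.0
    height: int = 120
    width: int = 160
    hr_bpm: float = 72.0
    modulation_amplitude: float = 0.01  # fraction of intensity
    motion: MotionSpec = field(default_factory=MotionSpec)
    shadow: ShadowSpec = field(default_factory=ShadowSpec)
    noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        f = self.hr_bpm / 60.0
        if not (0.8 < f < 3.0):
            raise ValueError("hr_bpm must map into the 0.8-3 Hz band")
        if self.fps <= 6.0:
            raise ValueError("fps must exceed twice the 3 Hz band edge")
        if self.duration <= 0 or self.modulation_amplitude < 0:
            raise ValueError("invalid scene configuration")


@dataclass
class SceneTruth:
    landmarks: np.ndarray  # (T, 478, 2) per-frame ground truth
    transforms: np.ndarray  # (T, 4): tx, ty, theta, s applied to the base
    hr_bpm: float
    pulse: np.ndarray  # clean pulse waveform at the video rate
    reference_ppg: np.ndarray  # 256 Hz paired PPG
    reference_fs: float
    shadowed_triangles: np.ndarray  # topology row indices inside the shadow
    skin_mask: np.ndarray  # (H, W) bool, canonical pose
    base_landmarks: np.ndarray  # (478, 2) canonical-pose layout


def _textured_background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    base = rng.uniform(0.25, 0.55, size=(h, w, 3))
    return ndimage.gaussian_filter(base, sigma=(2.5, 2.5, 0))


def _pulse_waveform(t: np.ndarray, f0: float) -> np.ndarray:
    """Fundamental plus a weak second harmonic, unit peak amplitude."""
    p = np.sin(2 * np.pi * f0 * t) + 0.3 * np.sin(4 * np.pi * f0 * t + 0.8)
    return p / np.max(np.abs(p))


def _apply_rigid(frame: np.ndarray, tx: float, ty: float, theta: float,
                 center: tuple[float, float]) -> np.ndarray:
    """Rotate about ``center`` then translate; bilinear, replicate border."""
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    cx, cy = center
    # forward map p' = R (p - c) + c + t  ->  inverse for resampling
    Rinv = R.T
    t_vec = np.array([tx, ty])
    ctr = np.array([cx, cy])
    P = np.array([[0.0, 1.0], [1.0, 0.0]])
    mat = P @ Rinv @ P
    off = P @ (ctr - Rinv @ (ctr + t_vec))
    out = np.empty_like(frame)
    for ch in range(3):
        out[..., ch] = ndimage.affine_transform(frame[..., ch], mat,
                                                offset=off, order=1,
                                                mode="nearest")
    return out


def make_scene(config: SceneConfig) -> tuple[FrameSequence, SceneTruth]:
    """Render the synthetic face scene and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    T = int(round(config.duration * config.fps))
    t = np.arange(T) / config.fps
    f0 = config.hr_bpm / 60.0

    center = (w / 2.0, h * 0.52)
    semi = (0.32 * w, 0.42 * h)
    yy, xx = np.mgrid[0:h, 0:w]
    ell = (((xx - center[0]) / semi[0]) ** 2
           + ((yy - center[1]) / semi[1]) ** 2)
    skin_mask = ell <= 1.0

    base = _textured_background(h, w, rng)
    skin_rgb = np.array([0.72, 0.55, 0.45])
    texture = 1.0 + 0.03 * ndimage.gaussian_filter(
        rng.standard_normal((h, w)), 1.2)
    for c in range(3):
        base[..., c] = np.where(skin_mask, skin_rgb[c] * texture, base[..., c])

    template = canonical_template()
    base_lm = template_to_frame(template, center, semi)

    # shadow region: one half of a cheek area, fixed in the face frame
    shadow_mask = np.zeros((h, w), dtype=bool)
    if config.shadow.enabled:
        sgn = 1.0 if config.shadow.side == "right" else -1.0
        shadow_mask = (skin_mask
                       & (sgn * (xx - center[0]) > 0.15 * semi[0])
                       & ((yy - center[1]) > -0.05 * semi[1]))
        lum = config.shadow.luminance_factor
        fac = np.array([lum, lum, min(1.0, lum * config.shadow.blue_shift)])
        for c in range(3):
            base[..., c] = np.where(shadow_mask, base[..., c] * fac[c],
                                    base[..., c])

    # which topology triangles fall inside the shadow (canonical pose)
    topo = default_topology()
    shadowed = []
    for i, row in enumerate(topo):
        cx_t, cy_t = base_lm[row].mean(axis=0)
        ix, iy = int(round(cx_t)), int(round(cy_t))
        if 0 <= ix < w and 0 <= iy < h and shadow_mask[iy, ix]:
            shadowed.append(i)

    pulse = _pulse_waveform(t, f0)
    a = config.modulation_amplitude

    m = config.motion
    ph = rng.uniform(0, 2 * np.pi, size=3)
    drift_x = m.drift_amplitude * np.sin(2 * np.pi * t / m.drift_period + ph[0])
    drift_y = m.drift_amplitude * np.sin(2 * np.pi * t / (m.drift_period * 1.3)
                                         + ph[1])
    drift_th = m.rot_drift_amplitude * np.sin(2 * np.pi * t
                                              / (m.drift_period * 1.1) + ph[2])
    jx = m.jitter_sd * rng.standard_normal(T)
    jy = m.jitter_sd * rng.standard_normal(T)
    jth = m.rot_jitter_sd * rng.standard_normal(T)
    theta_t = drift_th + jth
    if m.step_rotation:
        theta_t[T // 2:] += m.step_rotation
    tx_t = drift_x + jx
    ty_t = drift_y + jy

    frames = np.empty((T, h, w, 3))
    landmarks = np.empty((T, len(base_lm), 2))
    transforms = np.empty((T, 4))
    ctr = np.array(center)
    for k in range(T):
        frame = base.copy()
        delta = a * pulse[k]
        frame[..., 1] = np.where(skin_mask, frame[..., 1] - delta,
                                 frame[..., 1])
        frame[..., 0] = np.where(skin_mask, frame[..., 0] - 0.5 * delta,
                                 frame[..., 0])
        moved = (frame if (tx_t[k] == 0 and ty_t[k] == 0 and theta_t[k] == 0)
                 else _apply_rigid(frame, tx_t[k], ty_t[k], theta_t[k], center))
        if config.noise_sd > 0:
            moved = moved + config.noise_sd * rng.standard_normal(moved.shape)
        frames[k] = np.clip(moved, 0.0, 1.0)
        c_, s_ = np.cos(theta_t[k]), np.sin(theta_t[k])
        R = np.array([[c_, -s_], [s_, c_]])
        landmarks[k] = (base_lm - ctr) @ R.T + ctr + np.array([tx_t[k], ty_t[k]])
        transforms[k] = (tx_t[k], ty_t[k], theta_t[k], 1.0)

    ref_fs = 256.0
    ref = make_reference_ppg(np.full(int(round(config.duration * ref_fs)),
                                     config.hr_bpm),
                             fs=ref_fs, seed=config.seed + 1)
    truth = SceneTruth(landmarks=landmarks, transforms=transforms,
                       hr_bpm=config.hr_bpm, pulse=pulse, reference_ppg=ref,
                       reference_fs=ref_fs,
                       shadowed_triangles=np.asarray(shadowed, dtype=int),
                       skin_mask=skin_mask, base_landmarks=base_lm)
    return FrameSequence(frames=frames, fps=config.fps), truth


def make_mixture(n_channels: int, snr_db: float = 0.0, duration: float = 30.0,
                 fs: float = 20.0, hr_bpm: float = 72.0, seed: int = 0,
                 mixing: np.ndarray | None = None,
                 n_noise_sources: int | None = None):
    """Random full-rank mixture of one quasi-periodic pulse source and noise.

    The pulse has a 0.3-amplitude second harmonic and a slow frequency
    wander; the noise sources are AR(1) and white.  ``snr_db`` sets the
    per-channel pulse-to-noise power ratio.

    Returns ``(X, sources)`` with X (n_channels, T) and sources (k, T); the
    pulse source is row 0.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    rng = np.random.default_rng(seed)
    T = int(round(duration * fs))
    t = np.arange(T) / fs
    f0 = hr_bpm / 60.0
    wander = 0.03 * np.cumsum(rng.standard_normal(T)) / np.sqrt(T)
    phase = 2 * np.pi * np.cumsum(f0 * (1 + wander)) / fs
    pulse = np.sin(phase) + 0.3 * np.sin(2 * phase + 0.5)
    k = n_noise_sources if n_noise_sources is not None else n_channels - 1
    noise = []
    for i in range(k):
        if i % 2 == 0:
            e = rng.standard_normal(T)
            ar = np.empty(T)
            ar[0] = e[0]
            for n in range(1, T):
                ar[n] = 0.9 * ar[n - 1] + e[n]
            noise.append(ar)
        else:
            noise.append(rng.standard_normal(T))
    sources = np.vstack([pulse] + noise)
    sources = (sources - sources.mean(axis=1, keepdims=True))
    sources /= sources.std(axis=1, keepdims=True)
    if mixing is None:
        while True:
            mixing = rng.standard_normal((n_channels, sources.shape[0]))
            if np.linalg.matrix_rank(mixing) == min(mixing.shape):
                break
    gain = 10.0 ** (snr_db / 20.0)
    A = mixing.copy().astype(float)
    A[:, 0] *= gain
    X = A @ sources
    return X, sources


def _beat_shape(phase: np.ndarray) -> np.ndarray:
    """Two-bump beat morphology: systolic peak plus diastolic wave.

    The bump widths are broad enough that the fundamental dominates the
    spectrum, as in real PPG where the waveform is smooth rather than
    impulsive.
    """
    u = np.mod(phase, 1.0)
    sys_ = np.exp(-((u - 0.25) ** 2) / (2 * 0.11 ** 2))
    dia = 0.35 * np.exp(-((u - 0.45) ** 2) / (2 * 0.14 ** 2))
    return sys_ + dia


def make_reference_ppg(hr_trajectory_bpm: np.ndarray, fs: float = 256.0,
                       drift_amplitude: float = 0.2, noise_sd: float = 0.02,
                       seed: int = 0) -> np.ndarray:
    """Beat train with systolic/diastolic morphology, drift and noise.

    ``hr_trajectory_bpm`` gives the instantaneous HR per output sample.
    """
    hr = np.asarray(hr_trajectory_bpm, dtype=float)
    f = hr / 60.0
    if np.any((f <= 0.79) | (f >= 3.01)):
        raise ValueError("HR trajectory must stay inside the cardiac band")
    rng = np.random.default_rng(seed)
    n = hr.size
    t = np.arange(n) / fs
    phase = np.cumsum(f) / fs
    x = _beat_shape(phase)
    x = x + drift_amplitude * np.sin(2 * np.pi * t / 17.0 + rng.uniform(0, 2 * np.pi))
    x = x + noise_sd * rng.standard_normal(n)
    return x


def make_source_corpus(n_subjects: int = 10, mixtures_per_subject: int = 4,
                       n_channels: int = 10, duration: float = 30.0,
                       fs: float = 20.0, seed: int = 0):
    """Separated-source corpus for training the pulse/noise selector.

    Each pseudo-subject gets a characteristic HR and several mixtures at
    varying SNR; every mixture is separated with SOBI and cleaned exactly as
    in the pipeline, and each output source is labelled against the known
    pulse source.  Returns ``(features, labels, subjects)``.
    """
    from .selection import auto_annotate, featurize
    from .separation import cleanup_components, sobi

    rng = np.random.default_rng(seed)
    feats, labels, subjects = [], [], []
    for subj in range(n_subjects):
        hr = float(rng.uniform(55.0, 150.0))
        for m in range(mixtures_per_subject):
            snr = float(rng.uniform(-5.0, 10.0))
            mix_seed = int(rng.integers(0, 2 ** 31 - 1))
            X, src = make_mixture(n_channels, snr_db=snr, duration=duration,
                                  fs=fs, hr_bpm=hr, seed=mix_seed)
            try:
                res = sobi(X)
            except np.linalg.LinAlgError:
                continue
            cleaned = cleanup_components(res.sources, fs)
            for s in cleaned:
                feats.append(featurize(s, fs).features)
                labels.append(auto_annotate(s, src[0], fs))
                subjects.append(subj)
    return np.asarray(feats), np.asarray(labels, dtype=int), np.asarray(subjects)
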