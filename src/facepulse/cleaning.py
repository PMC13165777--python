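"""Trace-level artifact gating, harmonic suppression and outlier zeroing.

Gating uses the MAD-based modified z-score (robust to the trace's own pulse
peaks): traces whose outlier ratio exceeds 0.4 are discarded.  Harmonic
suppression places a Gaussian notch on the first harmonic 2*f0 and
redistributes the removed spectral magnitude to the fundamental bin in phase,
conserving total spectral magnitude.  Time-point outliers beyond 4 SD are
zeroed and the signal re-band-passed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .magnify import Episode

log = logging.getLogger(__name__)

__all__ = [
    "OutlierScore",
    "modified_zscore",
    "gate_traces",
    "bandpass_fft",
    "notch_transfer",
    "detect_fundamental",
    "harmonic_suppress",
    "zero_timepoint_outliers",
]

MAD_SCALE = 0.6745  # makes the modified z-score consistent with sigma for
# Gaussian data


@dataclass
class OutlierScore:
    scores: np.ndarray
    mask: np.ndarray  # |z| > z_thresh
    outlier_ratio: float
    n_outliers: int
    n_peaks: int


def modified_zscore(x: np.ndarray, z_thresh: float = 3.0) -> OutlierScore:
    """MAD-based modified z-scores; MAD = 0 means no outliers by convention."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        scores = np.zeros_like(x)
    else:
        scores = MAD_SCALE * (x - med) / mad
    mask = np.abs(scores) > z_thresh
    return OutlierScore(scores=scores, mask=mask, outlier_ratio=0.0,
                        n_outliers=int(mask.sum()), n_peaks=0)


def count_peaks(x: np.ndarray, fs: float, max_rate_hz: float = 3.0,
                prominence_frac: float = 0.5) -> int:
    """Local maxima with prominence >= 0.5 x SD and spacing >= fs/max_rate."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0
    peaks, _ = find_peaks(x, prominence=prominence_frac * sd,
                          distance=max(1, int(round(fs / max_rate_hz))))
    return int(len(peaks))


def outlier_ratio(x: np.ndarray, fs: float, z_thresh: float = 3.0) -> OutlierScore:
    """Outliers / (outliers + detected peaks); 0 when both counts are 0."""
    sc = modified_zscore(x, z_thresh)
    n_pk = count_peaks(x, fs)
    denom = sc.n_outliers + n_pk
    ratio = sc.n_outliers / denom if denom > 0 else 0.0
    return OutlierScore(scores=sc.scores, mask=sc.mask, outlier_ratio=ratio,
                        n_outliers=sc.n_outliers, n_peaks=n_pk)


def gate_traces(episode: Episode, ratio_thresh: float = 0.4,
                z_thresh: float = 3.0) -> Episode:
    """Drop traces whose outlier ratio strictly exceeds the threshold;
    surviving trace order is preserved."""
    keep = []
    for i, trace in enumerate(episode.signals):
        sc = outlier_ratio(trace, episode.fps, z_thresh)
        if sc.outlier_ratio <= ratio_thresh:
            keep.append(i)
    return Episode(signals=episode.signals[keep],
                   start_time=episode.start_time, fps=episode.fps,
                   triangle_ids=[episode.triangle_ids[i] for i in keep],
                   duration=episode.duration, overlap=episode.overlap,
                   truncated=episode.truncated)


def bandpass_fft(x: np.ndarray, fs: float, low: float = 0.8,
                 high: float = 3.0) -> np.ndarray:
    """Zero-phase ideal bandpass via the FFT (same filter as the EVM stage)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    F = np.fft.rfft(x, axis=-1)
    F[..., ~((freqs >= low) & (freqs <= high))] = 0.0
    return np.fft.irfft(F, n=n, axis=-1)


class SpectralError(ValueError):
    pass


def notch_transfer(f: np.ndarray | float, f0: float, sigma: float = 0.1,
                   alpha: float = 0.7) -> np.ndarray | float:
    """Gaussian notch H(f) = 1 - alpha * exp(-(f - 2 f0)^2 / (2 sigma^2)).

    Centered on the first harmonic 2*f0; ``1 - H(2 f0)`` equals the
    attenuation depth alpha.
    """
    f = np.asarray(f, dtype=float)
    out = 1.0 - alpha * np.exp(-((f - 2 * f0) ** 2) / (2 * sigma ** 2))
    return out if out.ndim else float(out)


def detect_fundamental(x: np.ndarray, fs: float,
                       band: tuple[float, float] = (0.8, 3.0),
                       half_energy_frac: float = 0.4) -> tuple[float, int]:
    """Locate the cardiac fundamental, guarding against harmonic dominance.

    The in-band magnitude peak is found first; if any bin within +-1 bin of
    its half-frequency carries more than ``half_energy_frac`` of the peak
    magnitude and lies in band, that half-frequency bin is the fundamental.

    Returns ``(f0_hz, f0_bin)`` over the rfft grid.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mag = np.abs(np.fft.rfft(x))
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise SpectralError("no FFT bins inside the band")
    idx = np.flatnonzero(in_band)
    peak = idx[np.argmax(mag[idx])]
    half = peak / 2.0
    cand_bins = np.array([int(np.floor(half)) - 1 + k for k in range(3)])
    cand_bins = cand_bins[(cand_bins > 0) & (cand_bins < len(freqs))]
    cand_bins = cand_bins[(freqs[cand_bins] >= band[0])
                          & (freqs[cand_bins] <= band[1])]
    if cand_bins.size:
        best = cand_bins[np.argmax(mag[cand_bins])]
        if mag[best] > half_energy_frac * mag[peak]:
            return float(freqs[best]), int(best)
    return float(freqs[peak]), int(peak)


def harmonic_suppress(x: np.ndarray, fs: float, sigma: float = 0.1,
                      alpha: float = 0.7,
                      band: tuple[float, float] = (0.8, 3.0),
                      half_energy_frac: float = 0.4,
                      f0: float | None = None) -> np.ndarray:
    """Gaussian notch at the first harmonic with in-phase energy return.

    The spectrum is multiplied by H(f) = 1 - alpha*exp(-(f-2f0)^2/(2 sigma^2))
    (mirrored at -2f0 so the output stays real); the magnitude removed within
    3 sigma of 2f0 is added back to the fundamental bin in phase with it.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if f0 is None:
        f0, f0_bin = detect_fundamental(x, fs, band, half_energy_frac)
    else:
        f0_bin = int(round(f0 * n / fs))
    if 2 * f0 > fs / 2:
        log.info("first harmonic above Nyquist; suppression skipped")
        return x.copy()
    F = np.fft.fft(x)
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    H = notch_transfer(np.abs(freqs), f0, sigma, alpha)
    before = np.abs(F)
    F_new = F * H
    notch_zone = np.abs(np.abs(freqs) - 2 * f0) <= 3 * sigma
    removed = before[notch_zone] - np.abs(F_new[notch_zone])
    # positive-frequency share of the removed magnitude
    delta_e = float(removed[freqs[notch_zone] > 0].sum())
    phi0 = np.angle(F[f0_bin])
    F_new[f0_bin] += delta_e * np.exp(1j * phi0)
    if f0_bin != 0 and f0_bin != n - f0_bin:
        F_new[n - f0_bin] += delta_e * np.exp(-1j * phi0)
    return np.real(np.fft.ifft(F_new))


def zero_timepoint_outliers(x: np.ndarray, fs: float, tau: float = 4.0,
                            band: tuple[float, float] = (0.8, 3.0),
                            refilter: bool = True) -> np.ndarray:
    """Zero samples beyond ``tau`` SD from the mean, then re-bandpass to
    smooth the discontinuities the zeroing introduces."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    mu, sd = x.mean(), x.std()
    out = x.copy()
    if sd > 0:
        out[np.abs(x - mu) > tau * sd] = 0.0
    if refilter:
        out = bandpass_fft(out, fs, *band)
    return out


def outlier_mask(x: np.ndarray, tau: float = 4.0) -> np.ndarray:
    """Boolean mask of |x - mean| > tau * SD (no replacement)."""
    x = np.asarray(x, dtype=float)
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=bool)
    return np.abs(x - mu) > tau * sd
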