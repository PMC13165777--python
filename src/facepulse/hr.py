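"""Back-projection, alignment, episode linking and HR estimation.

Selected SOBI components are propagated back through the SOBI mixing, the
global-PCA loadings and the window-PCA loadings into trace space; the
band-passed traces are lag-aligned, sign-corrected and averaged into one
representative trace per episode.  Consecutive episodes are linked over
their shared 15 s tail by a 2-trace PCA, and the heart rate is the dominant
FFT peak of the representative 15 s trace times 60.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cleaning import bandpass_fft
from .selection import SelectionResult
from .separation import GlobalPCAResult, SOBIResult, WindowPCAResult, zscore

log = logging.getLogger(__name__)

__all__ = [
    "HREstimate",
    "back_project",
    "align_and_average",
    "link_segments",
    "estimate_hr",
]


class PipelineStateError(RuntimeError):
    pass


@dataclass
class HREstimate:
    segment_start: float  # seconds
    hr_bpm: float | None
    mode: str  # classifier / fallback / null
    peak_hz: float | None = None


def back_project(selection: SelectionResult, sobi_result: SOBIResult,
                 global_result: GlobalPCAResult,
                 window_result: WindowPCAResult | None = None,
                 retained_idx: np.ndarray | None = None,
                 n_traces: int | None = None) -> np.ndarray:
    """Reconstruct denoised traces from the selected SOBI components.

    The selected sources propagate through the SOBI mixing (zeroing the
    others) into global-PC space, through the global loadings into the
    retained window-component space, and, when the window stage is supplied,
    through the window loadings into trace space (window overlaps averaged).
    Without a window stage the retained-component reconstruction is
    returned.
    """
    if not selection.indices:
        raise PipelineStateError("no components selected (null mode)")
    idx = np.asarray(selection.indices, dtype=int)
    contrib = sobi_result.mixing[:, idx] @ sobi_result.sources[idx]  # (k, T)
    comps = global_result.loadings @ contrib  # retained-component space
    if window_result is None:
        return comps
    if retained_idx is None:
        retained_idx = np.arange(comps.shape[0])
    if n_traces is None:
        n_traces = max(int(ids.max()) for ids in window_result.trace_indices) + 1
    T = comps.shape[1]
    acc = np.zeros((n_traces, T))
    cover = np.zeros(n_traces)
    for row, comp_idx in enumerate(retained_idx):
        w = window_result.window_of[comp_idx]
        # position of this component within its window's PC list
        pcs_in_w = [i for i, ww in enumerate(window_result.window_of) if ww == w]
        j = pcs_in_w.index(comp_idx)
        W = window_result.loadings[w]
        ids = window_result.trace_indices[w]
        acc[ids] += np.outer(W[:, j], comps[row])
        cover[ids] += 1
    used = cover > 0
    acc[used] /= cover[used, None]
    return acc[used]


def align_and_average(traces: np.ndarray, fs: float,
                      band: tuple[float, float] = (0.8, 3.0),
                      max_lag_s: float = 1.0) -> np.ndarray:
    """Band-pass, lag-align (max cross-correlation within +-max_lag_s),
    sign-correct and average the traces."""
    X = np.atleast_2d(np.asarray(traces, dtype=float))
    X = bandpass_fft(X, fs, *band)
    if X.shape[0] == 1:
        return X[0]
    Z = zscore(X)
    ref = Z[0]
    max_lag = int(round(max_lag_s * fs))
    aligned = [ref]
    for z in Z[1:]:
        full = np.correlate(ref, z, mode="full")
        lags = np.arange(-len(z) + 1, len(ref))
        ok = np.abs(lags) <= max_lag
        best = lags[ok][np.argmax(np.abs(full[ok]))]
        sign = np.sign(full[ok][np.argmax(np.abs(full[ok]))]) or 1.0
        aligned.append(sign * np.roll(z, best))
    return np.mean(aligned, axis=0)


def link_segments(current_tail: np.ndarray | None,
                  previous_tail: np.ndarray | None) -> np.ndarray | None:
    """Representative 15 s trace from two consecutive episode tails.

    Both valid: PCA on the stacked, z-scored pair; PC1's time course (sign
    set by positive correlation with the current tail).  One valid: that
    tail.  Neither: None.
    """
    if current_tail is None and previous_tail is None:
        return None
    if previous_tail is None:
        return np.asarray(current_tail, dtype=float)
    if current_tail is None:
        return np.asarray(previous_tail, dtype=float)
    X = zscore(np.stack([np.asarray(current_tail, dtype=float),
                         np.asarray(previous_tail, dtype=float)]))
    C = X @ X.T / X.shape[1]
    evals, evecs = np.linalg.eigh(C)
    w = evecs[:, np.argmax(evals)]
    pc1 = w @ X
    r = np.corrcoef(pc1, X[0])[0, 1]
    if r < 0:
        pc1 = -pc1
    return pc1


def estimate_hr(trace: np.ndarray, fs: float,
                band: tuple[float, float] = (0.8, 3.0),
                n_fft: int = 8192, segment_start: float = 0.0,
                mode: str = "classifier") -> HREstimate:
    """HR = 60 x the dominant in-band FFT peak of the representative trace.

    Zero-padding to ``n_fft`` refines the spectral grid well below the raw
    1/15 Hz bin spacing; ``n_fft=None`` uses the raw bins.
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0 or np.allclose(x, 0):
        return HREstimate(segment_start=segment_start, hr_bpm=None,
                          mode="null", peak_hz=None)
    n = max(n_fft or 0, x.size)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mag = np.abs(np.fft.rfft(x - x.mean(), n=n))
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    idx = np.flatnonzero(in_band)
    if idx.size == 0 or mag[idx].max() == 0:
        return HREstimate(segment_start=segment_start, hr_bpm=None,
                          mode="null", peak_hz=None)
    peak = freqs[idx[np.argmax(mag[idx])]]
    return HREstimate(segment_start=segment_start, hr_bpm=60.0 * float(peak),
                      mode=mode, peak_hz=float(peak))
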