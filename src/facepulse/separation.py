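"""Multi-stage blind source separation of the per-triangle traces.

The trace matrix is expanded by a sliding-window PCA over spatially adjacent
trace groups (2 PCs per window), thinned by correlation-based retention,
reduced by a global PCA capped at ten modes, and separated with SOBI (joint
diagonalization of time-lagged covariance matrices).  Every stage stores the
operators needed to back-project selected components to trace space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cleaning import bandpass_fft, harmonic_suppress, zero_timepoint_outliers

log = logging.getLogger(__name__)

__all__ = [
    "WindowPlan",
    "WindowPCAResult",
    "GlobalPCAResult",
    "SOBIResult",
    "plan_windows",
    "window_pca",
    "correlation_select",
    "global_pca",
    "sobi",
    "cleanup_components",
]


@dataclass
class WindowPlan:
    """Sliding windows over the trace index with adaptive width.

    width = min(max(floor(M/3), 5), M); stride 3; the final window is shifted
    left so it ends at M; duplicate starts are deduplicated.
    """

    M: int
    width: int
    starts: list[int]
    stride: int = 3


def plan_windows(M: int, stride: int = 3, min_width: int = 5) -> WindowPlan:
    if M < 1:
        raise ValueError("M must be >= 1")
    width = min(max(M // 3, min_width), M)
    starts = list(range(0, max(M - width, 0) + 1, stride))
    last = M - width
    if starts[-1] != last:
        starts.append(last)
    # dedupe while keeping order
    seen: set[int] = set()
    starts = [s for s in starts if not (s in seen or seen.add(s))]
    return WindowPlan(M=M, width=width, starts=starts, stride=stride)


def zscore(X: np.ndarray, axis: int = -1) -> np.ndarray:
    mu = X.mean(axis=axis, keepdims=True)
    sd = X.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


@dataclass
class WindowPCAResult:
    """Concatenated top-2 PCs of every window, with loadings for
    back-projection to trace space."""

    components: np.ndarray  # (K, T) component time courses
    window_of: list[int]  # window index per component
    loadings: list[np.ndarray]  # per window: (m_w, n_pcs) orthonormal
    trace_indices: list[np.ndarray]  # per window: trace ids in the window
    explained: np.ndarray  # explained-variance fraction per component


def window_pca(traces: np.ndarray, plan: WindowPlan | None = None,
               n_pcs: int = 2) -> WindowPCAResult:
    """Per-window PCA on z-scored traces; components are PC time courses."""
    X = np.asarray(traces, dtype=float)
    M = X.shape[0]
    if plan is None:
        plan = plan_windows(M)
    comps, winof, loadings, tidx, expl = [], [], [], [], []
    for w, s in enumerate(plan.starts):
        ids = np.arange(s, s + plan.width)
        sub = X[ids]
        keep = sub.std(axis=1) > 0
        if keep.sum() < n_pcs:
            log.info("window %d: fewer than %d varying traces, skipped", w, n_pcs)
            continue
        if not keep.all():
            log.info("window %d: %d zero-variance traces excluded",
                     w, int((~keep).sum()))
        ids = ids[keep]
        Z = zscore(sub[keep])
        # eigen-decomposition of the trace-by-trace covariance
        C = Z @ Z.T / Z.shape[1]
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:n_pcs]
        W = evecs[:, order]  # (m, n_pcs) orthonormal loadings
        pcs = W.T @ Z  # (n_pcs, T)
        total = evals.sum()
        for j in range(W.shape[1]):
            comps.append(pcs[j])
            winof.append(len(loadings))
            expl.append(evals[order][j] / total if total > 0 else 0.0)
        loadings.append(W)
        tidx.append(ids)
    if not comps:
        raise ValueError("no usable windows (all traces constant?)")
    return WindowPCAResult(components=np.stack(comps), window_of=winof,
                           loadings=loadings, trace_indices=tidx,
                           explained=np.asarray(expl))


def correlation_select(components: np.ndarray, corr_thresh: float = 0.5
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Retain components coherent with the most representative one.

    The representative maximizes the mean absolute Pearson correlation to
    all others; components whose |r| to it strictly exceeds the threshold
    (plus the representative itself) are retained.

    Returns ``(retained components, retained indices)``.
    """
    X = np.asarray(components, dtype=float)
    K = X.shape[0]
    if K < 2:
        return X, np.arange(K)
    Z = zscore(X)
    R = np.corrcoef(Z)
    R = np.nan_to_num(R)
    mean_abs = (np.abs(R).sum(axis=1) - 1.0) / (K - 1)
    rep = int(np.argmax(mean_abs))
    keep = np.abs(R[rep]) > corr_thresh
    keep[rep] = True
    idx = np.flatnonzero(keep)
    return X[idx], idx


@dataclass
class GlobalPCAResult:
    components: np.ndarray  # (k, T)
    loadings: np.ndarray  # (K, k) orthonormal projection
    explained: np.ndarray


def global_pca(components: np.ndarray, max_k: int = 10) -> GlobalPCAResult:
    """Top-min(K, max_k) PCs of the z-scored component stack."""
    X = zscore(np.asarray(components, dtype=float))
    K = X.shape[0]
    k = min(K, max_k)
    C = X @ X.T / X.shape[1]
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:k]
    W = evecs[:, order]  # (K, k)
    pcs = W.T @ X
    total = evals.sum()
    expl = evals[order] / total if total > 0 else np.zeros(k)
    return GlobalPCAResult(components=pcs, loadings=W, explained=expl)


@dataclass
class SOBIResult:
    sources: np.ndarray  # (n, T), unit variance
    mixing: np.ndarray  # (n, n): X ~ mixing @ sources
    unmixing: np.ndarray  # (n, n): sources = unmixing @ X
    converged: bool
    off_diag_history: list[float] = field(default_factory=list)


def _joint_diagonalize(mats: np.ndarray, tol: float = 1e-8,
                       max_sweeps: int = 100):
    """Jacobi joint diagonalization of symmetric matrices (rotation pairs).

    Returns ``(V, off_history, converged)`` with V orthogonal such that
    V.T @ M @ V is jointly as diagonal as possible.
    """
    K, n, _ = mats.shape
    V = np.eye(n)
    A = mats.copy()

    def off(A):
        return float(sum(np.sum(m ** 2) - np.sum(np.diag(m) ** 2) for m in A))

    history = [off(A)]
    converged = False
    for _ in range(max_sweeps):
        changed = False
        for p in range(n - 1):
            for q in range(p + 1, n):
                # closed-form Givens angle (Cardoso-Souloumiac, real case)
                h = np.array([A[:, p, p] - A[:, q, q], 2.0 * A[:, p, q]])
                G = h @ h.T
                evals, evecs = np.linalg.eigh(G)
                x, y = evecs[:, np.argmax(evals)]
                if x < 0:
                    x, y = -x, -y
                c = np.sqrt((x + 1) / 2.0)
                s = y / np.sqrt(2.0 * (x + 1))
                if abs(s) > tol:
                    changed = True
                    rot = np.eye(n)
                    rot[p, p] = rot[q, q] = c
                    rot[p, q] = -s
                    rot[q, p] = s
                    A = np.einsum("ij,kjl,lm->kim", rot.T, A, rot)
                    V = V @ rot
        history.append(off(A))
        if not changed:
            converged = True
            break
    return V, history, converged


def sobi(X: np.ndarray, lags: int | list[int] = 20, tol: float = 1e-8,
         max_sweeps: int = 100) -> SOBIResult:
    """Second-order blind identification by joint diagonalization of
    time-lagged covariance matrices of the whitened data."""
    X = np.asarray(X, dtype=float)
    n, T = X.shape
    if n < 2:
        raise ValueError("SOBI needs at least 2 channels")
    lag_list = list(range(1, lags + 1)) if np.isscalar(lags) else list(lags)
    if T <= max(lag_list):
        raise ValueError("series shorter than the largest lag")
    Xc = X - X.mean(axis=1, keepdims=True)
    C0 = Xc @ Xc.T / T
    evals, evecs = np.linalg.eigh(C0)
    evals = np.maximum(evals, 1e-12 * evals.max())
    Wh = evecs @ np.diag(evals ** -0.5) @ evecs.T  # symmetric whitener
    Z = Wh @ Xc
    mats = []
    for tau in lag_list:
        R = Z[:, :-tau] @ Z[:, tau:].T / (T - tau)
        mats.append(0.5 * (R + R.T))
    V, history, converged = _joint_diagonalize(np.stack(mats), tol, max_sweeps)
    if not converged:
        log.warning("SOBI joint diagonalization did not converge; "
                    "returning best iterate")
    unmixing = V.T @ Wh
    mixing = np.linalg.pinv(unmixing)
    sources = unmixing @ Xc
    sd = sources.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    mixing = mixing * sd.T
    sources = sources / sd
    unmixing = unmixing / sd
    # order components by descending back-projected power so "component 1"
    # is the dominant one
    power = (mixing ** 2).sum(axis=0)
    order = np.argsort(power)[::-1]
    sources = sources[order]
    mixing = mixing[:, order]
    unmixing = unmixing[order]
    return SOBIResult(sources=sources, mixing=mixing, unmixing=unmixing,
                      converged=converged, off_diag_history=history)


def cleanup_components(sources: np.ndarray, fs: float, sigma: float = 0.1,
                       alpha: float = 0.7, tau: float = 4.0,
                       band: tuple[float, float] = (0.8, 3.0)) -> np.ndarray:
    """Per component: harmonic suppression, outlier zeroing, re-bandpass."""
    out = []
    for s in np.asarray(sources, dtype=float):
        s = harmonic_suppress(s, fs, sigma=sigma, alpha=alpha, band=band)
        s = zero_timepoint_outliers(s, fs, tau=tau, band=band, refilter=False)
        s = bandpass_fft(s, fs, *band)
        out.append(s)
    return np.stack(out)
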