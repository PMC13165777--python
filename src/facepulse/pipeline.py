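"""End-to-end orchestration: video in, per-15 s HR out.

Stage order: landmarks -> canonical reference -> two-stage stabilization ->
tessellation + anatomical + chrominance ROI filtering -> per-episode EVM ->
green-trace extraction -> outlier gating -> per-trace harmonic suppression ->
sliding-window PCA -> correlation selection -> global PCA -> SOBI ->
component cleanup -> classifier/fallback selection -> back-projection,
alignment, episode linking -> FFT-peak HR.  Stage failures degrade to null
estimates per episode where recoverable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import cleaning, hr, magnify, roi, selection, separation, stabilize
from .config import PipelineConfig
from .video import (CanonicalReference, FrameSequence, LandmarkTrack,
                    build_canonical_reference, detect_landmarks)

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    estimates: list[hr.HREstimate]
    stage_log: dict = field(default_factory=dict)
    retained_triangles: list = field(default_factory=list)
    canonical: CanonicalReference | None = None


def _process_episode(episode: magnify.Episode, cfg: PipelineConfig, model,
                     representative_cache: dict) -> tuple[np.ndarray | None, str, dict]:
    """One 30 s episode -> (representative trace or None, mode, counters)."""
    fs = episode.fps
    band = cfg.band
    counters: dict = {"traces_in": episode.signals.shape[0]}
    gated = cleaning.gate_traces(episode, cfg.clean.ratio_thresh,
                                 cfg.clean.z_thresh)
    counters["traces_kept"] = gated.signals.shape[0]
    if gated.signals.shape[0] == 0:
        return None, "null", counters
    traces = np.stack([
        cleaning.harmonic_suppress(tr, fs, sigma=cfg.harm.sigma,
                                   alpha=cfg.harm.alpha, band=band,
                                   half_energy_frac=cfg.harm.half_energy_frac)
        for tr in gated.signals
    ])
    M = traces.shape[0]
    try:
        if cfg.sep.window_pca and M >= cfg.sep.n_pcs:
            plan = separation.plan_windows(M, stride=cfg.sep.stride)
            wres = separation.window_pca(traces, plan, n_pcs=cfg.sep.n_pcs)
            comps, kept_idx = separation.correlation_select(
                wres.components, cfg.sep.corr_thresh)
        else:
            wres, kept_idx = None, None
            comps = separation.zscore(traces)
        counters["components"] = comps.shape[0]
        gres = separation.global_pca(comps, max_k=cfg.sep.max_global)
        if gres.components.shape[0] < 2:
            # single mode: treat it directly as the physiological candidate
            rep = hr.align_and_average(gres.components, fs, band=band)
            return rep, "fallback", counters
        sres = separation.sobi(gres.components, lags=cfg.sep.sobi_lags)
        cleaned = separation.cleanup_components(
            sres.sources, fs, sigma=cfg.harm.sigma, alpha=cfg.harm.alpha,
            tau=cfg.clean.tau, band=band)
        sel = selection.select_components(
            model, cleaned, sres, fs, p_thresh=cfg.select.p_thresh,
            power_thresh=cfg.select.power_ratio_thresh
            if cfg.select.fallback else 1.1)
        counters["selected"] = len(sel.indices)
        counters["mode"] = sel.mode
        if sel.mode == "null":
            return None, "null", counters
        traces_rec = hr.back_project(sel, sres, gres, wres, kept_idx,
                                     n_traces=M)
        rep = hr.align_and_average(traces_rec, fs, band=band)
        return rep, sel.mode, counters
    except (np.linalg.LinAlgError, ValueError) as exc:
        log.warning("episode at %.0f s failed: %s", episode.start_time, exc)
        return None, "null", counters


def run_pipeline(video: FrameSequence, provider, cfg: PipelineConfig | None = None,
                 model=None) -> PipelineResult:
    """Run the full pipeline on a video with a landmark provider.

    ``model`` is the trained pulse/noise selector; None relies on the
    power-ratio fallback alone.
    """
    cfg = cfg or PipelineConfig()
    band = cfg.band
    stage_log: dict = {}

    track = detect_landmarks(video, provider)
    canonical = build_canonical_reference(track, n=cfg.landmarks.reference_frames)
    stage_log["frames"] = video.frame_count
    stage_log["detected_frames"] = int(track.detected.sum())

    if cfg.stab.enabled:
        state = stabilize.SmootherState(
            alpha_slow=cfg.stab.alpha_slow, alpha_fast=cfg.stab.alpha_fast,
            theta_threshold=cfg.stab.theta_threshold,
            alpha_step=cfg.stab.alpha_step)
        stab, stab_track, _, _ = stabilize.stabilize_video(
            video, track, canonical, state, refine=cfg.stab.refine)
    else:
        stab, stab_track = video, track

    rois = roi.select_rois(canonical, stab,
                           reference_uv=(cfg.roi.reference_u, cfg.roi.reference_v),
                           seed=cfg.seed, chrominance=cfg.roi.cluster)
    stage_log["triangles_retained"] = len(rois)
    if not rois:
        raise magnify.EmptyROIError("no retained triangles")

    fps = video.fps
    n_ep = int(round(cfg.episode.length * fps))
    step = int(round((cfg.episode.length - cfg.episode.overlap) * fps))
    T = video.frame_count
    starts = list(range(0, max(T - n_ep, 0) + 1, step)) or [0]

    estimates: list[hr.HREstimate] = []
    prev_tail: np.ndarray | None = None
    ep_counters = []
    tail_n = int(round(cfg.episode.overlap * fps))
    for s0 in starts:
        chunk = FrameSequence(frames=stab.frames[s0:s0 + n_ep], fps=fps)
        if cfg.evm.enabled:
            mag = magnify.magnify_video(chunk, rois, canonical.points,
                                        alpha=cfg.evm.alpha,
                                        level=cfg.evm.level, band=band)
        else:
            mag = chunk
        eps = magnify.extract_episodes(mag, rois, canonical.points,
                                       duration=chunk.frame_count / fps,
                                       overlap=cfg.episode.overlap)
        episode = eps[0]
        episode.start_time = s0 / fps
        if cfg.hr.postprocess:
            rep, mode, counters = _process_episode(episode, cfg, model, {})
        else:
            rep = cleaning.bandpass_fft(episode.signals.mean(axis=0), fps, *band)
            mode, counters = "classifier", {"traces_in": episode.signals.shape[0]}
        ep_counters.append(counters)
        cur_tail = rep[-tail_n:] if rep is not None else None
        linked = hr.link_segments(cur_tail, prev_tail)
        seg_start = s0 / fps + cfg.episode.length - cfg.episode.overlap
        if linked is None:
            estimates.append(hr.HREstimate(segment_start=seg_start,
                                           hr_bpm=None, mode="null"))
        else:
            est = hr.estimate_hr(linked, fps, band=band, n_fft=cfg.hr.n_fft,
                                 segment_start=seg_start, mode=mode)
            estimates.append(est)
        prev_tail = cur_tail
    stage_log["episodes"] = ep_counters
    return PipelineResult(estimates=estimates, stage_log=stage_log,
                          retained_triangles=rois, canonical=canonical)
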