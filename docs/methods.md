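# Methods

`facepulse` estimates heart rate (HR) from face video by remote
photoplethysmography (rPPG): the cardiac pulse modulates skin blood volume,
which modulates diffuse skin reflectance by a fraction of a percent,
strongest in the green channel. The pipeline is a sequential mitigation
chain — each stage attenuates one nuisance (motion, uneven illumination,
sensor/compression noise, harmonic ambiguity) — followed by blind source
separation and a supervised selection of the physiological component.

## Pipeline model and assumptions

1. **Landmarks and canonical face.** A pluggable provider supplies 478
   facial landmarks per frame. The subject-specific canonical face is the
   per-landmark mean over the first 15 reliably detected frames. Assumption:
   the head pose in those frames is representative; frames where detection
   fails reuse the previous smoothed transform.
2. **Two-stage stabilization.** Stage 1 estimates a 4-DOF similarity
   (translation, in-plane rotation θ, isotropic scale s) from current
   landmarks to the canonical layout by least squares (Umeyama), then
   smooths each parameter with an exponential moving average
   p̂ₜ = (1−α) p̂ₜ₋₁ + α pₜ. The baseline α_slow = 0.05 suppresses
   frame-to-frame estimation jitter; when |θₜ − θ̂ₜ₋₁| > 0.05 rad a
   correction phase ramps α by +0.15 per frame toward α_fast = 0.8 and
   resets to α_slow on the first frame back under threshold (the ramp
   schedule is our choice; any monotone ramp settling within ~5 frames
   behaves equivalently). Stage 2 removes residual *horizontal* translation:
   two facial-boundary points are tracked between consecutive stabilized
   frames with an iterative Lucas–Kanade patch tracker (21×21 window,
   bilinear subpixel sampling, ~0.05 px accuracy on textured synthetic
   frames), and the mean horizontal displacement from the canonical
   x-positions is subtracted. Tracking re-anchors to the landmark positions
   each frame so flow errors cannot accumulate.
3. **ROI tessellation and filtering.** The canonical face is tessellated
   into small triangles (Delaunay over the 478-point layout); triangles
   whose canonical centroid falls inside the forehead or cheek polygons
   (boundary counts as inside) are candidates. A 2-means clustering of each
   triangle's temporal-mean chrominance (U, V) keeps the cluster nearest a
   configurable well-lit-skin reference point, default (30, 45) on the
   0–255 scale. Chrominance convention: Y is BT.601 luma and
   U = 0.492 (Y − B), V = 0.877 (R − Y) — the U axis is oriented so warm,
   well-lit skin is positive in both coordinates and therefore near the
   reference point, while shadowed/bluish regions fall away from it. The
   exact numbers are uncritical since clustering adapts per scene; only the
   orientation matters.
4. **Eulerian video magnification (EVM).** Stabilized frames are converted
   to YIQ, decomposed with a Gaussian pyramid (5-tap binomial kernel, level
   3 = 1/8 scale), band-passed 0.8–3.0 Hz per masked pixel with an ideal
   FFT-domain filter, multiplied by α = 50, cubic-upsampled and added back.
   Saturation is prevented per pixel by scaling the delta with
   k = min over channels of (1−I)/ΔI (positive ΔI) or −I/ΔI (negative),
   clipped to [0, 1]; frames are then quantized to 8 bits. Magnification is
   applied per 30 s episode so memory stays bounded; the ideal bandpass is
   zero-phase, so per-episode filtering does not shift the pulse.
5. **Traces and gating.** Per-triangle mean green traces (0–255 scale) are
   segmented into 30 s episodes with 15 s overlap. Traces are gated by the
   MAD-based modified z-score z = 0.6745 (x − median)/MAD: samples with
   |z| > 3 are outliers, and a trace is discarded when
   outliers/(outliers + detected peaks) > 0.4 (strict). The peak detector —
   unspecified in the underlying method — is local maxima with prominence
   ≥ 0.5 SD and spacing ≥ fs/3 Hz samples, matching the top of the cardiac
   band. MAD = 0 means no outliers (constant traces carry no spikes).
6. **Harmonic suppression.** The in-band FFT peak is checked for being a
   first harmonic: if any bin within ±1 bin of its half frequency carries
   > 40% of the peak magnitude, that bin is the fundamental f₀. A Gaussian
   notch H(f) = 1 − 0.7·exp(−(f−2f₀)²/(2·0.1²)) is applied (mirrored at
   −2f₀ to keep the signal real); the magnitude removed within 3σ of 2f₀ is
   added back to the fundamental bin in phase (FFT(f₀) += ΔE·e^{iφ₀}), so
   total spectral magnitude is conserved. Applied per trace before
   separation and again per separated component.
7. **Separation.** Traces are ordered spatially (forehead, then left and
   right cheek, by canonical centroid), z-scored, and expanded by a
   sliding-window PCA: window width min(max(⌊M/3⌋, 5), M), stride 3, final
   window clamped to end at M, duplicate starts deduplicated, 2 PCs per
   window. Components are thinned by correlation: the component with the
   highest mean |Pearson r| to all others is the representative, and
   components with |r| > 0.5 to it are retained. A global PCA caps the set
   at 10 modes, and SOBI (whitening + Jacobi joint diagonalization of
   lagged covariances, lags 1–20 samples = 1 s at 20 fps, tolerance 1e-8,
   ≤ 100 sweeps) yields unit-variance sources ordered by back-projected
   power. Each source is cleaned (harmonic suppression, τ = 4 SD time-point
   zeroing, re-bandpass).
8. **Selection.** Each source is represented by time-averaged wavelet
   scattering coefficients (orders 0–2) of the z-scored signal and of its
   biased autocorrelation (lags 0..T/2, lag-0 = 1). The scattering
   transform is implemented in-package as an FFT-domain Morlet filter-bank
   cascade with J = 6 octaves, Q = 8 first-order wavelets per octave, one
   second-order wavelet per octave (second-order paths restricted to
   ξ₂ < ξ₁/2), global time averaging — 129 coefficients per input, 258 per
   source. A LightGBM classifier (200 trees, depth ≤ 6, learning rate 0.05,
   balanced class weights) outputs pulse probabilities; components with
   p > 0.35 are selected. If none clears the threshold, the first SOBI
   component is selected alone when its power ratio (variance of its
   back-projected contribution over the summed contributions) exceeds 0.75;
   otherwise the episode yields a **null** estimate — a deliberate fail-safe
   rather than a guess.
9. **Reconstruction and HR.** Selected sources are back-projected through
   the SOBI mixing, global-PCA loadings and window-PCA loadings into trace
   space (window overlaps averaged); traces are band-passed, lag-aligned
   (±1 s, sign-corrected) and averaged. Consecutive episodes are linked:
   the final 15 s of the current and previous episodes are stacked,
   z-scored, and PC1 (sign set by positive correlation with the current
   tail) is the representative 15 s trace; a null neighbour passes the
   other tail through. HR = 60 × the dominant 0.8–3 Hz FFT peak,
   zero-padded to 8192 samples (~0.15 bpm grid; the raw 15 s window gives
   4 bpm bins, too coarse for bpm-level accuracy). HR is always in
   [48, 180] bpm or null.

## Reference processing and evaluation

The reference PPG (256 Hz) is mean-removed, resampled to 20 Hz, detrended
with the smoothness-priors method (λ = 120), band-passed with a 3rd-order
zero-phase Butterworth (0.8–3 Hz), normalized by its Hilbert envelope
(floored at 10⁻⁶ of its median), segmented into 15 s windows, and the FFT
peak × 60 is the reference HR. **Ordering note:** the regularized
detrender's cutoff scales with the sampling rate — λ = 120 at 256 Hz would
remove everything below ≈ 3.7 Hz, i.e. the entire cardiac band (we verified
numerically that the fundamental is attenuated ~200× there, leaving the
harmonics dominant). At the 20 Hz working rate the same λ removes only
sub-0.3 Hz baseline wander, which is the evident intent, so detrending is
applied after resampling.

Agreement metrics: MAE, RMSE, MER (= 100·mean |e|/ref), Pearson r, and
Bland–Altman bias ± 1.96 SD limits of agreement (sample SD). Null estimates
are excluded pairwise and counted.

## Synthetic data

The scene generator renders a skin-toned ellipse (RGB ≈ 0.72/0.55/0.45) on
a smoothed-noise background with mild multiplicative skin texture, and
injects the pulse as ΔG = −a·p(t), ΔR = −a/2·p(t) on skin pixels (blood
absorption lowers reflectance; green strongest). p(t) is a unit-normalized
fundamental plus 0.3-amplitude second harmonic. Defaults emulate a
challenging consumer-video condition: 60 s at 20 fps, 160×120, modulation
amplitude 0.01 (≈ 1% of intensity, the upper end of real rPPG contrast —
appropriate because the generator omits video-compression artifacts),
translation drift of 3 px amplitude with ~40 s period, white translation
jitter SD 1.5 px, rotational drift 0.035 rad (≈ 2°, below the 0.05 rad
correction threshold) with white rotational jitter SD 0.01 rad, one cheek
shadowed (luminance ×0.5 with a bluish chrominance shift), pixel noise SD
0.01. Rotational drift is included because realistic head motion wanders
slowly; without it the "before" rotation statistic would consist solely of
white jitter, which no causal parameter smoother can remove from the
residual. The paired 256 Hz reference PPG is a two-Gaussian (systolic +
diastolic) beat train with baseline drift and noise; bump widths are broad
enough that the fundamental dominates the spectrum, as in real, smooth PPG
waveforms.

What the generator does **not** model: photorealistic faces, out-of-plane
rotation, specular highlights, time-varying illumination, and codec
compression artifacts. Passing tests therefore demonstrate the pipeline's
signal-path correctness and its motion/illumination robustness mechanisms,
not performance on any real dataset.

The mixture generator (`make_mixture`) produces random full-rank mixtures
of a quasi-periodic pulse (slow frequency wander, 0.3 second harmonic) with
AR(1) and white noise sources at a stated per-channel SNR; the selector's
training corpus is built by running SOBI + cleanup on such mixtures and
labelling each output against the known pulse (|r| ≥ 0.7 and FFT peaks
within 1 bin).

## Numerical choices and degenerate inputs

- All temporal band-passing inside the pipeline is the same ideal
  zero-phase FFT filter; the reference path uses the Butterworth stated for
  it.
- Similarity decomposition/reconstruction is exact for 4-DOF transforms;
  warping uses bilinear interpolation with replicated borders (no dark
  frame edges contaminating ROI means).
- K-means uses k = 2, 10 restarts, fixed seed; a tie in
  centroid-to-reference distance retains both clusters (fail-open). Fewer
  than 2 candidate triangles skips clustering.
- Rasterization counts pixels whose centers satisfy inclusive barycentric
  edge tests; degenerate triangles rasterize to the empty set.
- SOBI non-convergence after 100 sweeps returns the best iterate with a
  warning; the off-diagonal criterion is non-increasing by construction.
- Constant traces: MAD = 0 ⇒ no outliers; zero-variance traces are excluded
  from their PCA window; an all-zero representative trace yields a null HR.
- Episodes shorter than 30 s are processed truncated and flagged.

## Problem sizes used in validation

Synthetic validation uses 60 s scenes at 160×120 / 20 fps (three 15 s
estimates each), 10-channel mixtures of 30 s for separation checks, and a
~300-source corpus over 10 pseudo-subjects for selector cross-validation.
These sizes exercise every stage at full fidelity while keeping the whole
suite desk-scale; accuracy at these sizes is limited by the spectral grid
(~0.15 bpm), not by the scene duration.

## Known limitations

- The landmark-provider adapter for a real face-mesh detector is untested
  here (no detector ships with the package); all validation uses the
  synthetic provider.
- The 478-point canonical layout and its region polygons are synthetic
  stand-ins with the same cardinality and topology contract as common
  face-mesh models, not anatomical meshes.
- Episode linking follows the stated procedure (PCA over the two episodes'
  final 15 s tails) even though those tails cover different wall-clock
  windows; it stabilizes rate estimates but is not a waveform merge.
- The selector is trained on synthetic mixtures; applying the pipeline to
  real video requires retraining on annotated real sources (CLI `train`).
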