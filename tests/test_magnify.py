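import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from facepulse.magnify import (AliasingError, EmptyROIError,
                               FrameTooSmallError, amplify_and_reconstruct,
                               build_pyramid_band, extract_episodes,
                               magnify_video, rgb_to_yiq, saturation_clamp,
                               temporal_bandpass, yiq_to_rgb, _blur_decimate,
                               _BINOMIAL5)
from facepulse.roi import TriangleROI
from facepulse.video import FrameSequence


def _video(frames, fps=20.0):
    return FrameSequence(frames=np.asarray(frames, dtype=float), fps=fps)


class TestPyramid:
    def test_dc_preservation(self):
        v = _video(np.full((3, 32, 32, 3), 0.47))
        band = build_pyramid_band(v, level=3)
        assert band.shape == (3, 4, 4, 3)
        y = rgb_to_yiq(np.full(3, 0.47))[0]
        np.testing.assert_allclose(band[..., 0], y, atol=1e-9)

    def test_impulse_matches_explicit_convolution(self):
        # oracle: one blur+decimate step as explicit separable convolution
        from scipy import ndimage

        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        expected = ndimage.convolve1d(
            ndimage.convolve1d(img, _BINOMIAL5, axis=0, mode="nearest"),
            _BINOMIAL5, axis=1, mode="nearest")[::2, ::2]
        np.testing.assert_allclose(_blur_decimate(img), expected)

    def test_too_small_raises(self):
        v = _video(np.zeros((2, 4, 4, 3)))
        with pytest.raises(FrameTooSmallError):
            build_pyramid_band(v, level=3)


class TestTemporalBandpass:
    def _band(self, signal, h=4, w=4):
        return np.tile(signal[:, None, None, None], (1, h, w, 3))

    def test_dc_rejected(self):
        band = self._band(np.full(100, 3.3))
        out = temporal_bandpass(band, fps=20.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_inband_unit_gain(self):
        t = np.arange(200) / 20.0
        a = 0.37
        band = self._band(a * np.sin(2 * np.pi * 1.5 * t))
        out = temporal_bandpass(band, fps=20.0)
        amp = (out[:, 0, 0, 0].max() - out[:, 0, 0, 0].min()) / 2
        assert amp == pytest.approx(a, rel=1e-6)

    def test_stopband_rejected(self):
        t = np.arange(200) / 20.0
        band = self._band(np.sin(2 * np.pi * 5.0 * t))
        out = temporal_bandpass(band, fps=20.0)
        assert np.abs(out).max() < 1e-9

    def test_mask_respected(self):
        band = np.random.default_rng(0).normal(size=(100, 4, 4, 3))
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 2] = True
        out = temporal_bandpass(band, fps=20.0, mask=mask)
        assert np.abs(out[:, 0, 0]).max() == 0.0
        assert np.abs(out[:, 1, 2]).max() > 0.0

    def test_aliasing_guard(self):
        band = np.zeros((50, 4, 4, 3))
        with pytest.raises(AliasingError):
            temporal_bandpass(band, fps=5.0, high=3.0)


class TestAmplify:
    def test_zero_band_is_identity(self):
        rng = np.random.default_rng(0)
        v = _video(rng.uniform(0.2, 0.8, (5, 16, 16, 3)))
        out = amplify_and_reconstruct(v, np.zeros((5, 2, 2, 3)), alpha=50)
        np.testing.assert_allclose(out, v.frames, atol=1e-9)

    def test_alpha_zero_identity(self):
        rng = np.random.default_rng(1)
        v = _video(rng.uniform(0.2, 0.8, (5, 16, 16, 3)))
        band = rng.normal(0, 0.01, (5, 2, 2, 3))
        out = amplify_and_reconstruct(v, band, alpha=0)
        np.testing.assert_allclose(out, v.frames, atol=1e-9)

    def test_uniform_modulation_gain_is_alpha(self):
        # spatially uniform in-band luma modulation: added delta = alpha * band
        T, H, W = 40, 16, 16
        t = np.arange(T) / 20.0
        mod = 1e-4 * np.sin(2 * np.pi * 1.5 * t)
        v = _video(np.full((T, H, W, 3), 0.5))
        band = np.zeros((T, 2, 2, 3))
        band[..., 0] = mod[:, None, None]  # Y channel
        out = amplify_and_reconstruct(v, band, alpha=50.0)
        delta_y = rgb_to_yiq(out - v.frames)[..., 0]
        amp_delta = (delta_y[:, 8, 8].max() - delta_y[:, 8, 8].min()) / 2
        amp_band = (mod.max() - mod.min()) / 2
        assert amp_delta / amp_band == pytest.approx(50.0, rel=0.02)


class TestSaturationClamp:
    def test_zero_delta_identity(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0, 1, (4, 4, 3))
        out = saturation_clamp(f, f.copy())
        np.testing.assert_allclose(out, np.round(f * 255) / 255)

    def test_stated_formula_example(self):
        orig = np.array([[[0.9, 0.5, 0.5]]])
        mag = orig + np.array([[[0.2, 0.1, 0.0]]])
        out = saturation_clamp(orig, mag)
        # k = min(0.1/0.2, 0.5/0.1, 1) = 0.5 -> R = 0.9 + 0.5*0.2 = 1.0
        assert out[0, 0, 0] == pytest.approx(1.0)
        assert out[0, 0, 1] == pytest.approx(0.55, abs=1 / 255)

    @given(st.integers(0, 10 ** 6))
    def test_output_always_in_range(self, seed):
        rng = np.random.default_rng(seed)
        orig = rng.uniform(0, 1, (10, 10, 3))
        mag = orig + rng.normal(0, 0.5, (10, 10, 3))
        out = saturation_clamp(orig, mag)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_k_is_one_when_no_saturation(self):
        orig = np.full((2, 2, 3), 0.5)
        mag = orig + 0.1
        out = saturation_clamp(orig, mag)
        np.testing.assert_allclose(out, np.round(0.6 * 255) / 255)


class TestEpisodes:
    def _tri(self):
        return TriangleROI(vertex_indices=(0, 1, 2),
                           centroid=np.array([2.0, 2.0]))

    def test_constant_green_trace(self):
        frames = np.zeros((10, 8, 8, 3))
        frames[..., 1] = 0.25
        lm = np.zeros((478, 2))
        lm[:3] = [(0, 0), (6, 0), (0, 6)]
        eps = extract_episodes(_video(frames), [self._tri()], lm,
                               duration=0.5, overlap=0.25)
        np.testing.assert_allclose(eps[0].signals, 0.25 * 255)

    def test_60s_video_gives_three_episodes(self):
        frames = np.zeros((1200, 8, 8, 3))
        lm = np.zeros((478, 2))
        lm[:3] = [(0, 0), (6, 0), (0, 6)]
        eps = extract_episodes(_video(frames), [self._tri()], lm)
        assert [e.start_time for e in eps] == [0.0, 15.0, 30.0]
        assert all(e.signals.shape[1] == 600 for e in eps)

    def test_no_triangles_raises(self):
        with pytest.raises(EmptyROIError):
            extract_episodes(_video(np.zeros((10, 8, 8, 3))), [],
                             np.zeros((478, 2)))

    def test_short_video_truncated_flag(self):
        frames = np.zeros((100, 8, 8, 3))
        lm = np.zeros((478, 2))
        lm[:3] = [(0, 0), (6, 0), (0, 6)]
        eps = extract_episodes(_video(frames), [self._tri()], lm)
        assert len(eps) == 1 and eps[0].truncated


class TestMagnifyVideo:
    def test_masked_out_pixels_unchanged(self, still_scene):
        _, video, truth = still_scene
        chunk = FrameSequence(frames=video.frames[:100], fps=video.fps)
        tri = TriangleROI(vertex_indices=(0, 1, 2), centroid=np.zeros(2))
        lm = np.zeros((478, 2))
        lm[:3] = [(60.0, 50.0), (80.0, 50.0), (60.0, 70.0)]
        mag = magnify_video(chunk, [tri], lm)
        # far corner is outside the dilated ROI mask: identical up to 8-bit
        orig_q = np.round(chunk.frames[:, :8, -8:] * 255) / 255
        np.testing.assert_allclose(mag.frames[:, :8, -8:], orig_q, atol=1e-12)

    def test_trace_peak_at_injected_frequency(self, still_scene):
        from facepulse.roi import select_rois
        from facepulse.video import (SyntheticLandmarkProvider,
                                     build_canonical_reference,
                                     detect_landmarks)

        cfg, video, truth = still_scene
        track = detect_landmarks(video, SyntheticLandmarkProvider(truth.landmarks))
        canon = build_canonical_reference(track)
        rois = select_rois(canon, video, seed=0)
        chunk = FrameSequence(frames=video.frames[:600], fps=video.fps)
        mag = magnify_video(chunk, rois, canon.points)
        eps = extract_episodes(mag, rois, canon.points)
        tr = eps[0].signals
        freqs = np.fft.rfftfreq(tr.shape[1], 1 / video.fps)
        df = freqs[1]
        f_true = cfg.hr_bpm / 60.0
        for trace in tr[:: max(1, len(tr) // 20)]:
            spec = np.abs(np.fft.rfft(trace - trace.mean()))
            assert abs(freqs[np.argmax(spec)] - f_true) <= df + 1e-9
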