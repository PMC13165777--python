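import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from facepulse.separation import (cleanup_components, correlation_select,
                                  global_pca, plan_windows, sobi, window_pca,
                                  zscore)
from facepulse.synth import make_mixture


class TestWindowPlan:
    def test_m9(self):
        plan = plan_windows(9)
        assert plan.width == 5
        assert plan.starts == [0, 3, 4]

    def test_m30_width(self):
        assert plan_windows(30).width == 10

    def test_m4_single_clamped_window(self):
        plan = plan_windows(4)
        assert plan.width == 4
        assert plan.starts == [0]

    @given(st.integers(1, 200))
    def test_coverage_and_width_bounds(self, M):
        plan = plan_windows(M)
        assert min(5, M) <= plan.width <= M
        covered = np.zeros(M, dtype=bool)
        for s in plan.starts:
            assert 0 <= s and s + plan.width <= M
            covered[s:s + plan.width] = True
        assert covered.all()
        assert plan.starts == sorted(set(plan.starts))


class TestWindowPCA:
    def test_rank_one_input(self):
        t = np.arange(600) / 20.0
        sig = np.sin(2 * np.pi * 1.2 * t)
        traces = np.tile(sig, (6, 1)) * np.array([[1], [2], [3], [1.5], [2.5], [0.5]])
        res = window_pca(traces)
        assert res.explained[0] > 0.999
        r = np.corrcoef(res.components[0], sig)[0, 1]
        assert abs(r) > 0.9999

    def test_two_orthogonal_modes_recovered(self):
        t = np.arange(600) / 20.0
        s1 = np.sin(2 * np.pi * 1.0 * t)
        s2 = np.sin(2 * np.pi * 1.7 * t)
        traces = np.stack([s1, s1, s2, s2, s1 + 0.01 * s2])
        res = window_pca(traces, plan_windows(5))
        # eigen-decomposition oracle: both modes appear among the PCs
        cors = np.abs(np.corrcoef(np.vstack([res.components, s1, s2]))
                      [: len(res.components), len(res.components):])
        assert cors[:, 0].max() > 0.99
        assert cors[:, 1].max() > 0.99

    def test_coherent_pulse_beats_single_traces(self, rng):
        t = np.arange(600) / 20.0
        pulse = np.sin(2 * np.pi * 1.2 * t)
        traces = np.stack([pulse + rng.normal(0, 1.0, 600) for _ in range(10)])
        res = window_pca(traces)
        pc1 = res.components[0]
        r_pc = abs(np.corrcoef(pc1, pulse)[0, 1])
        r_traces = np.mean([abs(np.corrcoef(tr, pulse)[0, 1]) for tr in traces])
        assert r_pc > r_traces

    def test_loadings_orthonormal(self, rng):
        traces = rng.normal(size=(12, 300))
        res = window_pca(traces)
        for W in res.loadings:
            np.testing.assert_allclose(W.T @ W, np.eye(W.shape[1]), atol=1e-8)


class TestCorrelationSelect:
    def test_identical_all_retained(self):
        x = np.tile(np.sin(np.linspace(0, 20, 300)), (4, 1))
        kept, idx = correlation_select(x)
        assert len(idx) == 4

    def test_noise_component_discarded(self, rng):
        t = np.arange(300) / 20.0
        pulse = np.sin(2 * np.pi * 1.2 * t)
        comps = np.stack([pulse, pulse * 2, -pulse, rng.normal(size=300)])
        kept, idx = correlation_select(comps)
        assert set(idx) == {0, 1, 2}

    @pytest.mark.parametrize("target_r,expect_kept", [
        (0.499, False), (0.5, False), (0.501, True)])
    def test_threshold_is_strict(self, target_r, expect_kept):
        # component whose |r| to the representative sits at/below 0.5 is
        # dropped; strictly above is kept
        rng = np.random.default_rng(0)
        a = rng.normal(size=4000)
        b = rng.normal(size=4000)
        a = (a - a.mean()) / a.std()
        b = b - (a @ b) / (a @ a) * a  # exactly orthogonal to a
        b = (b - b.mean()) / b.std()
        b = b - (a @ b) / (a @ a) * a
        # mix with measured correlation steered onto the target
        mix = target_r * a + np.sqrt(1 - target_r ** 2) * b
        r_emp = np.corrcoef(a, mix)[0, 1]
        mix = mix + (target_r - r_emp) * a  # first-order correction
        comps = np.stack([a, a * 1.1, a * 0.9, mix])
        kept, idx = correlation_select(comps)
        r_final = abs(np.corrcoef(a, mix)[0, 1])
        # the rule is strict: kept iff |r| > 0.5 as actually computed
        assert (3 in idx) == (r_final > 0.5)
        if target_r != 0.5:  # away from the float boundary the outcome is fixed
            assert (3 in idx) == expect_kept

    def test_single_component_passthrough(self):
        x = np.sin(np.linspace(0, 10, 100))[None]
        kept, idx = correlation_select(x)
        np.testing.assert_array_equal(kept, x)


class TestGlobalPCA:
    def test_no_padding(self, rng):
        res = global_pca(rng.normal(size=(4, 200)))
        assert res.components.shape[0] == 4

    def test_cap_at_ten(self, rng):
        res = global_pca(rng.normal(size=(25, 200)))
        assert res.components.shape[0] == 10

    def test_rank3_reconstruction(self, rng):
        basis = rng.normal(size=(3, 400))
        mix = rng.normal(size=(8, 3))
        X = mix @ basis
        Xz = zscore(X)
        res = global_pca(X)
        recon = res.loadings @ res.components
        np.testing.assert_allclose(recon, Xz, atol=1e-8)


class TestSOBI:
    def test_known_orthogonal_mixing_recovered(self):
        t = np.arange(600) / 20.0
        s1 = np.sin(2 * np.pi * 1.0 * t)
        s2 = np.sin(2 * np.pi * 1.7 * t)
        th = 0.6
        A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        X = A @ np.stack([s1, s2])
        res = sobi(X)
        cors = np.abs(np.corrcoef(np.vstack([res.sources, s1, s2]))[:2, 2:])
        # each true source matched by some output with |r| > 0.99
        assert cors.max(axis=0).min() > 0.99

    def test_uncorrelated_input_fixed_point(self):
        # channels already uncorrelated at all lags: sources equal the
        # inputs up to permutation/sign/scale
        t = np.arange(800) / 20.0
        X = np.stack([np.sin(2 * np.pi * 0.9 * t),
                      np.sin(2 * np.pi * 2.3 * t)])
        res = sobi(X)
        M = np.abs(np.corrcoef(np.vstack([res.sources, X]))[:2, 2:])
        assert (M.max(axis=1) > 0.999).all()
        assert (M.max(axis=0) > 0.999).all()

    def test_unmixing_mixing_identity(self, rng):
        X, _ = make_mixture(6, snr_db=0.0, seed=3)
        res = sobi(X)
        np.testing.assert_allclose(res.unmixing @ res.mixing, np.eye(6),
                                   atol=1e-6)

    def test_off_diagonal_non_increasing(self):
        X, _ = make_mixture(8, snr_db=0.0, seed=5)
        res = sobi(X)
        h = np.asarray(res.off_diag_history)
        assert (np.diff(h) <= 1e-10).all()

    def test_recovers_pulse_from_mixture(self):
        X, src = make_mixture(10, snr_db=-5.0, seed=11)
        res = sobi(X)
        r = max(abs(np.corrcoef(s, src[0])[0, 1]) for s in res.sources)
        assert r >= 0.95


class TestCleanup:
    def test_clean_inband_sinusoid_unchanged(self):
        t = np.arange(600) / 20.0
        x = np.sin(2 * np.pi * 1.2 * t)
        out = cleanup_components(x[None], 20.0)[0]
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_strong_harmonic_suppressed(self):
        t = np.arange(600) / 20.0
        x = np.sin(2 * np.pi * 1.2 * t) + 1.2 * np.sin(2 * np.pi * 2.4 * t)
        out = cleanup_components(x[None], 20.0)[0]
        freqs = np.fft.rfftfreq(600, 1 / 20.0)
        assert freqs[np.argmax(np.abs(np.fft.rfft(out)))] == pytest.approx(1.2)

    def test_spike_zeroed_and_band_limited(self, rng):
        t = np.arange(600) / 20.0
        x = np.sin(2 * np.pi * 1.2 * t)
        x[300] += 10.0
        out = cleanup_components(x[None], 20.0)[0]
        freqs = np.fft.rfftfreq(600, 1 / 20.0)
        spec = np.abs(np.fft.rfft(out))
        assert spec[freqs > 3.01].max() < 1e-9
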