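"""Windowed wavelet coherence estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmcpipe import wavelet_coherence
from cmcpipe.coherence import (
    DEFAULT_BANDS,
    BandDefinition,
    CoherenceSpectrum,
    WindowingConfig,
    band_mean,
    band_peak_frequency,
    participant_peak_cf,
)
from cmcpipe.wavelets import WaveletBank

from conftest import make_analysis_pair


class TestWaveletCoherence:
    def test_self_coherence_is_one(self, bank, wincfg, rng):
        x = rng.standard_normal(wincfg.n_samples)
        spec = wavelet_coherence(x, x, bank, wincfg)
        np.testing.assert_allclose(spec.coherence, 1.0, atol=1e-10)

    def test_symmetry_exact(self, bank, wincfg, rng):
        x = rng.standard_normal(wincfg.n_samples)
        y = rng.standard_normal(wincfg.n_samples)
        a = wavelet_coherence(x, y, bank, wincfg).coherence
        b = wavelet_coherence(y, x, bank, wincfg).coherence
        np.testing.assert_array_equal(a, b)

    def test_amplitude_scale_invariance(self, bank, wincfg, rng):
        x = rng.standard_normal(wincfg.n_samples)
        y = rng.standard_normal(wincfg.n_samples)
        a = wavelet_coherence(x, y, bank, wincfg).coherence
        b = wavelet_coherence(17.3 * x, -0.002 * y, bank, wincfg).coherence
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_window_resolution_matches_printed_value(self, wincfg):
        assert abs(wincfg.resolution_hz(250.0) - 0.504) < 0.001

    def test_independent_noise_bias_below_point_nine(self, bank, wincfg):
        means = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            x = r.standard_normal(wincfg.n_samples)
            y = r.standard_normal(wincfg.n_samples)
            means.append(wavelet_coherence(x, y, bank, wincfg).coherence.mean())
        assert np.mean(means) < 0.9
        # small-sample bias for 8 averaged windows sits far above zero too
        assert 0.1 < np.mean(means) < 0.6

    def test_null_bias_decreases_with_window_length(self, bank):
        """The window-averaged-modulus estimator's noise bias is governed by
        the amount of within-window time averaging: longer windows -> lower
        bias on independent noise."""
        sub = bank.subset(8.0, 30.0)
        means = {}
        for ws in (248, 496):
            cfg = WindowingConfig(n_windows=8, window_samples=ws)
            vals = []
            for seed in range(40):
                r = np.random.default_rng(100 + seed)
                x = r.standard_normal(cfg.n_samples)
                y = r.standard_normal(cfg.n_samples)
                vals.append(wavelet_coherence(x, y, sub, cfg).coherence.mean())
            means[ws] = np.mean(vals)
        assert means[496] < means[248]

    def test_null_variance_decreases_with_more_windows(self, bank):
        """More averaged windows reduce the variance of the estimate."""
        sub = bank.subset(8.0, 30.0)
        spreads = {}
        for n_win in (4, 16):
            cfg = WindowingConfig(n_windows=n_win, window_samples=248)
            vals = []
            for seed in range(60):
                r = np.random.default_rng(500 + seed)
                x = r.standard_normal(cfg.n_samples)
                y = r.standard_normal(cfg.n_samples)
                vals.append(wavelet_coherence(x, y, sub, cfg).coherence.mean())
            spreads[n_win] = np.std(vals)
        assert spreads[16] < spreads[4]

    def test_coupled_trial_exceeds_empirical_null(self, bank, wincfg):
        """Coherence at the coupling frequency on a driven trial beats the
        95th percentile of the independent-drive null."""
        sub = bank.subset(16.0, 26.0)
        _, analysis = make_analysis_pair(seed=5)
        coupled = wavelet_coherence(
            analysis.channel("C3")[: wincfg.n_samples],
            analysis.channel("ExO")[: wincfg.n_samples],
            sub,
            wincfg,
        ).coherence.max()
        null = []
        for seed in range(20):
            _, seg = make_analysis_pair(seed=200 + seed, direction="none")
            null.append(
                wavelet_coherence(
                    seg.channel("C3")[: wincfg.n_samples],
                    seg.channel("ExO")[: wincfg.n_samples],
                    sub,
                    wincfg,
                ).coherence.max()
            )
        assert coupled > np.percentile(null, 95)

    def test_nan_input_rejected(self, bank, wincfg):
        x = np.zeros(wincfg.n_samples)
        x[0] = np.nan
        with pytest.raises(ValueError):
            wavelet_coherence(x, x, bank, wincfg)

    def test_wrong_length_rejected(self, bank, wincfg):
        x = np.zeros(wincfg.n_samples + 1)
        with pytest.raises(ValueError):
            wavelet_coherence(x, x, bank, wincfg)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.01, 100.0))
    def test_boundedness_fuzzed(self, seed, scale):
        bank = WaveletBank(cfs=np.array([5.0, 10.0, 20.0]))
        cfg = WindowingConfig(n_windows=2, window_samples=64)
        r = np.random.default_rng(seed)
        x = scale * r.standard_normal(cfg.n_samples)
        y = r.standard_normal(cfg.n_samples) ** 3  # heavy-tailed
        coh = wavelet_coherence(x, y, bank, cfg).coherence
        assert np.all(coh >= 0.0) and np.all(coh <= 1.0)


class TestBandSummaries:
    def _spec(self, values, cfs=None):
        cfs = np.asarray(cfs if cfs is not None else WaveletBank().cfs)
        return CoherenceSpectrum(np.asarray(values, float), cfs, 8)

    def test_band_mean_of_constant(self, bank):
        spec = self._spec(np.full(bank.n_cfs, 0.37))
        assert band_mean(spec, DEFAULT_BANDS["alpha"]) == pytest.approx(0.37)

    def test_band_mean_hand_computed(self, bank):
        vals = np.linspace(0.1, 0.9, bank.n_cfs)
        alpha_idx = [i for i, c in enumerate(bank.cfs) if 8 <= c <= 12]
        expected = np.mean([vals[i] for i in alpha_idx])
        spec = self._spec(vals)
        assert band_mean(spec, DEFAULT_BANDS["alpha"]) == pytest.approx(expected)

    def test_band_mean_singleton_band(self, bank):
        vals = np.linspace(0.0, 1.0, bank.n_cfs)
        cf = bank.cfs[10]
        band = BandDefinition("one", cf - 0.01, cf + 0.01)
        assert band_mean(self._spec(vals), band) == pytest.approx(vals[10])

    def test_empty_band_rejected(self, bank):
        with pytest.raises(ValueError):
            band_mean(self._spec(np.ones(bank.n_cfs)), BandDefinition("x", 200.0, 300.0))

    def test_peak_frequency_argmax(self, bank):
        vals = np.zeros(bank.n_cfs)
        alpha_idx = [i for i, c in enumerate(bank.cfs) if 8 <= c <= 12]
        vals[alpha_idx[1]] = 0.8
        spec = self._spec(vals)
        assert band_peak_frequency(spec, DEFAULT_BANDS["alpha"]) == bank.cfs[alpha_idx[1]]

    def test_peak_frequency_flat_ties_to_lowest(self, bank):
        spec = self._spec(np.full(bank.n_cfs, 0.5))
        lo = min(c for c in bank.cfs if 8 <= c <= 12)
        assert band_peak_frequency(spec, DEFAULT_BANDS["alpha"]) == lo

    def test_peak_frequency_recovers_injected_coupling(self, bank, wincfg):
        """Coupling injected at 21 Hz shows a beta-band peak within one cf step."""
        peak_seg, _ = make_analysis_pair(seed=21)
        win4 = wincfg.for_segment(peak_seg.n_samples)
        spec = wavelet_coherence(
            peak_seg.channel("C3")[: win4.n_samples],
            peak_seg.channel("ExO")[: win4.n_samples],
            bank,
            win4,
        )
        cf = band_peak_frequency(spec, DEFAULT_BANDS["beta"])
        beta_cfs = bank.cfs[(bank.cfs >= 13) & (bank.cfs <= 30)]
        k = int(np.argmin(np.abs(beta_cfs - cf)))
        assert abs(beta_cfs[k] - 21.0) <= np.max(np.diff(beta_cfs))

    def test_participant_peak_snaps_to_bank(self, bank):
        out = participant_peak_cf(np.array([9.9, 11.6, 8.3]), bank)
        assert out in bank.cfs
        assert out == bank.cfs[np.argmin(np.abs(bank.cfs - np.mean([9.9, 11.6, 8.3])))]
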