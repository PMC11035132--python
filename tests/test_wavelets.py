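import numpy as np
import pytest

from dmdc import (
    Epoch,
    MorletPower,
    WaveletConfig,
    band_average,
    count_events,
    gen_lfp_composite,
    morlet_transform,
    registry,
    zscore_power,
)
from dmdc.filters import BAND_NAMES

FS = 1000.0


def sine_epoch(freq, n=3000, amp=1.0):
    t = np.arange(n) / FS
    return Epoch(samples=amp * np.sin(2 * np.pi * freq * t), fs=FS)


def small_cfg():
    return WaveletConfig(freqs=tuple(float(f) for f in range(4, 61)), n_cycles=7)


class TestMorletTransform:
    def test_peak_frequency_of_pure_sine(self):
        pm = morlet_transform(sine_epoch(8.0), small_cfg())
        mean_power = pm.values.mean(axis=0)
        assert pm.freqs[int(np.argmax(mean_power))] == 8.0

    def test_zero_signal_zero_power(self):
        pm = morlet_transform(Epoch(samples=np.zeros(3000), fs=FS), small_cfg())
        assert np.all(pm.values == 0.0)

    def test_power_nonnegative(self, rng):
        pm = morlet_transform(Epoch(samples=rng.standard_normal(3000), fs=FS),
                              small_cfg())
        assert np.all(pm.values >= 0.0)

    def test_too_low_frequency_dropped_with_warning(self):
        ep = Epoch(samples=np.zeros(2500), fs=FS)
        with pytest.warns(UserWarning, match="support exceeds"):
            pm = morlet_transform(ep)
        assert 1.0 not in pm.freqs and 2.0 in pm.freqs

    def test_filterbank_gain_matches_fft_oracle(self):
        # a real unit sine carries amplitude 1/2 at +f0, so the complex
        # wavelet output has constant power |K(f0)|^2 / 4
        from dmdc.wavelets import _morlet_kernel

        f0 = 20.0
        ep = sine_epoch(f0, n=6000)
        cfg = WaveletConfig(freqs=(f0,), n_cycles=7)
        pm = morlet_transform(ep, cfg)
        measured = pm.values[1000:-1000, 0].mean()
        kernel = _morlet_kernel(f0, FS, 7)
        gain = np.abs(np.fft.fft(kernel, 1 << 16))
        f_axis = np.fft.fftfreq(1 << 16, 1 / FS)
        k_at_tone = gain[np.argmin(np.abs(f_axis - f0))]
        assert measured == pytest.approx(k_at_tone**2 / 4.0, rel=0.10)


class TestZScore:
    def test_columns_standardized(self, rng):
        pm = morlet_transform(Epoch(samples=rng.standard_normal(3000), fs=FS),
                              small_cfg())
        z = zscore_power(pm)
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=0), 1.0, atol=1e-9)

    def test_zero_signal_all_zero_with_warning(self):
        pm = morlet_transform(Epoch(samples=np.zeros(3000), fs=FS), small_cfg())
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_power(pm)
        assert np.all(z.values == 0.0)

    def test_double_zscore_rejected(self, rng):
        pm = morlet_transform(Epoch(samples=rng.standard_normal(3000), fs=FS),
                              small_cfg())
        z = zscore_power(pm)
        with pytest.raises(ValueError, match="already"):
            zscore_power(z)


class TestBandSummaries:
    def _flat_map(self, theta_value=0.0):
        freqs = tuple(float(f) for f in range(4, 61))
        values = np.zeros((2000, len(freqs)))
        theta_rows = [i for i, f in enumerate(freqs) if 4 <= f <= 12]
        values[:, theta_rows] = theta_value
        from dmdc.wavelets import PowerMap

        return PowerMap(values=values, fs=FS, freqs=freqs, zscored=True)

    def test_all_zero_map_zero_average(self):
        assert band_average(self._flat_map(), registry()["theta"]) == 0.0

    def test_band_selectivity(self):
        pm = self._flat_map(theta_value=1.0)
        assert band_average(pm, registry()["theta"]) == 1.0
        assert band_average(pm, registry()["slow_gamma"]) == 0.0

    def test_zero_series_zero_events(self):
        s = count_events(self._flat_map(), registry()["theta"], band_name="theta")
        assert s.event_count == 0 and s.event_rate == 0.0

    def test_single_sustained_crossing_is_one_event(self):
        pm = self._flat_map()
        theta_rows = [i for i, f in enumerate(pm.freqs) if 4 <= f <= 12]
        pm.values[500:, theta_rows] = 3.0  # crosses up once, stays up
        s = count_events(pm, registry()["theta"])
        assert s.event_count == 1

    def test_event_rate_is_count_per_second(self):
        pm = self._flat_map()
        theta_rows = [i for i, f in enumerate(pm.freqs) if 4 <= f <= 12]
        for start in (100, 600, 1100):
            pm.values[start : start + 50, theta_rows] = 4.0
        s = count_events(pm, registry()["theta"])
        assert s.event_count == 3
        assert s.event_rate == pytest.approx(3 / 2.0)  # 2000 samples at 1 kHz

    def test_sample_mode_counts_samples(self):
        pm = self._flat_map()
        theta_rows = [i for i, f in enumerate(pm.freqs) if 4 <= f <= 12]
        pm.values[100:150, theta_rows] = 4.0
        s = count_events(pm, registry()["theta"], event_mode="samples")
        assert s.event_count == 50

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError, match="threshold"):
            count_events(self._flat_map(), registry()["theta"], threshold=0.0)

    def test_wavelet_band_set_excludes_swr(self):
        assert set(BAND_NAMES) == {"theta", "slow_gamma", "fast_gamma"}


class TestBurstRecovery:
    def test_theta_burst_dominates_band_average(self):
        # averaged over the burst window: z-scoring makes the full-extent
        # average identically zero, so the comparison lives on a sub-window
        hits = 0
        n_seeds = 20
        window = (0.8, 1.3)
        for seed in range(n_seeds):
            e = gen_lfp_composite(
                burst_spec=[("theta", 0.8, 0.5, 4.0)], seed=seed
            )
            pm = MorletPower(freqs=tuple(float(f) for f in range(2, 102))).fit(
                e
            ).transform(e)
            theta = band_average(pm, registry()["theta"], window=window)
            slow = band_average(pm, registry()["slow_gamma"], window=window)
            hits += theta > slow
        assert hits == n_seeds

    def test_scheduled_bursts_recovered_as_events(self):
        # z_amp=4 bursts should be detected in >=90% of seeds
        ok = 0
        n_seeds = 50
        for seed in range(n_seeds):
            # a 10 s trial: bursts must be sparse relative to the z-scoring
            # extent, else they dominate their own normalization
            e = gen_lfp_composite(
                n=10000,
                burst_spec=[("theta", 0.5, 0.4, 4.0), ("theta", 4.0, 0.4, 4.0),
                            ("theta", 8.0, 0.4, 4.0)],
                seed=seed,
            )
            pm = MorletPower(freqs=tuple(float(f) for f in range(2, 102))).fit(
                e
            ).transform(e)
            s = count_events(pm, registry()["theta"])
            ok += s.event_count >= 3
        assert ok >= 0.9 * n_seeds
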