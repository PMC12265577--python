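"""Spike binning, PSD estimation against a direct-DFT oracle, band power,
and the FIFO observation window."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seadbs.biomarker import (BetaBandSpec, BiomarkerConfig, ObservationWindow,
                              PsdEstimate, beta_power, estimate_psd,
                              spikes_to_signal)
from seadbs.raster import SpikeRaster


def dft_periodogram(x, fs):
    """Independent one-sided periodogram straight from the DFT definition."""
    x = np.asarray(x, dtype=float)
    n = x.size
    X = np.array([np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
                  for k in range(n // 2 + 1)])
    p = np.abs(X) ** 2 / (fs * n)
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    freqs = np.arange(n // 2 + 1) * fs / n
    return freqs, p


class TestSpikesToSignal:
    def test_empty_raster_is_all_zero(self):
        r = SpikeRaster([np.empty(0)] * 3, 0.0, 10.0)
        sig = spikes_to_signal(r, 0.5)
        assert sig.shape == (3, 20)
        assert not sig.any()

    def test_spike_placement(self):
        r = SpikeRaster([np.array([1.0])], 0.0, 4.0)
        sig = spikes_to_signal(r, 0.5)
        assert sig[0, 2] == 1
        assert sig.sum() == 1

    @given(st.lists(st.floats(0.001, 99.9), min_size=0, max_size=50))
    @settings(max_examples=50)
    def test_count_conservation(self, times):
        times = np.unique(np.round(times, 4))
        r = SpikeRaster([times], 0.0, 100.0)
        assert spikes_to_signal(r, 0.5).sum() == times.size

    def test_zero_length_window_rejected(self):
        r = SpikeRaster([np.empty(0)], 5.0, 5.0)
        with pytest.raises(ValueError):
            spikes_to_signal(r, 0.5)

    def test_bin_width_domain(self):
        r = SpikeRaster([np.empty(0)], 0.0, 10.0)
        with pytest.raises(ValueError):
            spikes_to_signal(r, 2.0)


class TestEstimatePsd:
    fs = 2000.0
    cfg = BiomarkerConfig(method="periodogram")

    def _signals(self):
        t = np.arange(1024) / self.fs
        rng = np.random.default_rng(7)
        return {
            "sine20": np.sin(2 * np.pi * 20.0 * t),
            "sine50": np.sin(2 * np.pi * 50.0 * t),
            "noise": rng.standard_normal(1024),
        }

    @pytest.mark.parametrize("name", ["sine20", "sine50", "noise"])
    def test_matches_direct_dft(self, name):
        x = self._signals()[name]
        psd = estimate_psd(x, self.fs, self.cfg)
        f_ref, p_ref = dft_periodogram(x, self.fs)
        assert psd.freqs == pytest.approx(f_ref)
        scale = p_ref.max()
        assert np.max(np.abs(psd.power - p_ref)) / scale < 1e-6

    def test_sine_peak_location(self):
        x = self._signals()["sine20"]
        psd = estimate_psd(x, self.fs, self.cfg)
        peak = psd.freqs[np.argmax(psd.power)]
        grid_near_20 = psd.freqs[np.argmin(np.abs(psd.freqs - 20.0))]
        assert peak == pytest.approx(grid_near_20)

    def test_parseval(self):
        x = self._signals()["noise"]
        psd = estimate_psd(x, self.fs, self.cfg)
        df = psd.freqs[1] - psd.freqs[0]
        assert psd.power.sum() * df == pytest.approx(np.mean(x**2), rel=0.05)

    def test_all_zero_signal(self):
        psd = estimate_psd(np.zeros(1024), self.fs, self.cfg)
        assert not psd.power.any()

    def test_band_unresolvable(self):
        with pytest.raises(ValueError):
            estimate_psd(np.zeros(1024), 50.0, self.cfg)

    def test_welch_needs_full_segment(self):
        cfg = BiomarkerConfig(method="welch", segment=256.0)
        with pytest.raises(ValueError):
            estimate_psd(np.zeros(100), 2000.0, cfg)


class TestBetaPower:
    def test_unit_density_rectangle(self):
        f = np.arange(0.0, 101.0)
        p = np.where((f >= 13) & (f <= 35), 1.0, 0.0)
        psd = PsdEstimate(f, p)
        assert beta_power(psd) == pytest.approx(22.0)

    def test_averaging_idempotent_and_order_invariant(self, rng):
        f = np.linspace(0, 100, 201)
        row = rng.uniform(size=f.size)
        one = beta_power(PsdEstimate(f, row))
        two = beta_power(PsdEstimate(f, np.vstack([row, row])))
        assert one == pytest.approx(two)
        a, b = rng.uniform(size=(2, f.size))
        fwd = beta_power(PsdEstimate(f, np.vstack([a, b])))
        rev = beta_power(PsdEstimate(f, np.vstack([b, a])))
        assert fwd == pytest.approx(rev)

    def test_linearity(self, rng):
        f = np.linspace(0, 100, 201)
        p = rng.uniform(size=f.size)
        assert beta_power(PsdEstimate(f, 3.0 * p)) == pytest.approx(
            3.0 * beta_power(PsdEstimate(f, p))
        )

    @given(lo=st.floats(5.0, 12.9), hi=st.floats(35.1, 60.0))
    @settings(max_examples=50)
    def test_band_nesting_monotone(self, lo, hi):
        """Widening the integration band never decreases band power."""
        rng = np.random.default_rng(3)
        f = np.linspace(0, 100, 201)
        psd = PsdEstimate(f, rng.uniform(size=f.size))
        inner = beta_power(psd, BetaBandSpec(13.0, 35.0))
        outer = beta_power(psd, BetaBandSpec(lo, hi))
        assert outer >= inner - 1e-12

    def test_band_outside_grid(self):
        psd = PsdEstimate(np.linspace(0, 20, 21), np.ones(21))
        with pytest.raises(ValueError):
            beta_power(psd)

    def test_modulated_raster_frequency_discrimination(self, rng):
        """Rasters rate-modulated at 20 Hz carry more beta power than
        equal-count rasters modulated at 50 Hz."""
        def modulated(freq):
            dt, dur, base = 0.0005, 4.096, 60.0
            t = np.arange(0, dur, dt)
            lam = base * (1 + 0.9 * np.sin(2 * np.pi * freq * t)) * dt
            gen = np.random.default_rng(42)
            spikes = t[gen.uniform(size=t.size) < lam] * 1000.0
            return SpikeRaster([spikes], 0.0, dur * 1000.0)

        cfg = BiomarkerConfig()
        vals = {}
        for freq in (20.0, 50.0):
            sig = spikes_to_signal(modulated(freq), cfg.bin_width)
            psd = estimate_psd(sig, cfg.fs, cfg)
            vals[freq] = beta_power(psd, cfg.band)
        assert vals[20.0] > vals[50.0]


class TestRasterIO:
    def test_text_round_trip(self, tmp_path, rng):
        spikes = [np.sort(rng.uniform(0, 100, size=rng.integers(0, 20)))
                  for _ in range(5)]
        spikes = [np.unique(s) for s in spikes]
        r = SpikeRaster(spikes, 0.0, 100.0)
        path = tmp_path / "raster.txt"
        r.to_text(path)
        back = SpikeRaster.from_text(path)
        assert (back.t0, back.t1) == (r.t0, r.t1)
        assert back.n_spikes == r.n_spikes
        for a, b in zip(r.spikes, back.spikes):
            assert b == pytest.approx(a, abs=1e-4)

    def test_invalid_rasters_rejected(self):
        with pytest.raises(ValueError):
            SpikeRaster([np.array([2.0, 1.0])], 0.0, 10.0)  # not increasing
        with pytest.raises(ValueError):
            SpikeRaster([np.array([11.0])], 0.0, 10.0)  # outside window


class TestObservationWindow:
    def test_fifo_and_mean(self):
        w = ObservationWindow(n_obs=2, values=np.array([0.2, 0.4]))
        w.push(0.6)
        assert w.values == pytest.approx([0.4, 0.6])
        assert w.mean == pytest.approx(0.5)

    def test_constant_stream(self):
        w = ObservationWindow(n_obs=5)
        for _ in range(12):
            w.push(0.3)
        assert w.mean == pytest.approx(0.3)
        assert w.fill_count == 5

    def test_degenerate_single_slot(self):
        w = ObservationWindow(n_obs=1)
        for v in (0.1, 0.9, 0.4):
            w.push(v)
            assert w.mean == pytest.approx(v)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50)
    def test_mean_matches_stored_values(self, vals):
        w = ObservationWindow(n_obs=5)
        for v in vals:
            w.push(v)
        assert w.mean == pytest.approx(np.mean(vals[-5:]))
        assert w.fill_count == min(len(vals), 5)

    def test_vector_padding_and_fill_flag(self):
        w = ObservationWindow(n_obs=4)
        w.push(0.5)
        assert not w.filled
        assert w.as_vector() == pytest.approx([0.0, 0.0, 0.0, 0.5])
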