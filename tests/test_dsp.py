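"""Filter design/application, decimation, epoching, Welch spectra, band powers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from bciloop import (
    EEGSession,
    FilterSpec,
    PSD,
    apply_filter,
    band_power,
    decimate,
    design_butterworth,
    make_epochs,
    welch_psd,
)


def _mag_db(sos, f, fs):
    w, h = sps.sosfreqz(sos, worN=[2 * np.pi * f / fs])
    return 20 * np.log10(np.abs(h[0]))


class TestDesignButterworth:
    def test_minus_3db_at_cutoff(self):
        sos = design_butterworth(FilterSpec("lowpass", 8.5, fs=256))
        assert -3.5 <= _mag_db(sos, 8.5, 256) <= -2.5

    def test_dc_behaviour(self):
        lp = design_butterworth(FilterSpec("lowpass", 8.5, fs=256))
        hp = design_butterworth(FilterSpec("highpass", 3.5, fs=256))
        w, h = sps.sosfreqz(lp, worN=[1e-9])
        assert abs(abs(h[0]) - 1) < 1e-6
        w, h = sps.sosfreqz(hp, worN=[1e-9])
        assert abs(h[0]) < 1e-6

    def test_octave_attenuation(self):
        # order-2 lowpass rolls off ~12 dB/octave
        sos = design_butterworth(FilterSpec("lowpass", 5.0, fs=256))
        assert _mag_db(sos, 10.0, 256) <= -10.0

    def test_stability(self):
        for spec in (FilterSpec("bandpass", (11.75, 12.25), fs=256),
                     FilterSpec("lowpass", 8.5, fs=256),
                     FilterSpec("highpass", 3.5, fs=32)):
            sos = design_butterworth(spec)
            _, poles, _ = sps.sos2zpk(sos)
            assert np.all(np.abs(poles) < 1.0)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec("lowpass", 128.0, fs=256)
        with pytest.raises(ValueError):
            FilterSpec("bandpass", (8.0, 5.0), fs=256)


class TestApplyFilter:
    band = design_butterworth(FilterSpec("bandpass", (3.5, 8.5), fs=256))

    def test_zero_in_zero_out(self):
        assert np.allclose(apply_filter(np.zeros((3, 500)), self.band), 0)

    @pytest.mark.parametrize("freq,lo,hi", [(5.0, 0.7, 1.1), (20.0, 0.0, 0.3)])
    def test_passband_stopband_rms(self, freq, lo, hi):
        t = np.arange(256 * 8) / 256
        x = np.sin(2 * np.pi * freq * t)
        y = apply_filter(x, self.band)
        ratio = y.std() / x.std()
        assert lo <= ratio <= hi

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            apply_filter(np.zeros(10), self.band)

    def test_linearity(self, rng):
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        a, b = 2.5, -0.7
        lhs = apply_filter(a * x + b * y, self.band)
        rhs = a * apply_filter(x, self.band) + b * apply_filter(y, self.band)
        assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-9)


class TestDecimate:
    def test_length_division(self):
        assert decimate(np.zeros(512), 256, 32).shape == (64,)

    def test_constant_preserved(self):
        out = decimate(np.full(512, 3.7), 256, 32)
        assert np.allclose(out, 3.7)

    def test_low_tone_survives_with_antialias(self):
        t = np.arange(512) / 256
        y = decimate(np.sin(2 * np.pi * 4 * t), 256, 32, anti_alias=True)
        ideal = np.sin(2 * np.pi * 4 * np.arange(64) / 32)
        assert np.corrcoef(y, ideal)[0, 1] > 0.99

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            decimate(np.zeros(100), 256, 48)


class TestMakeEpochs:
    def test_window_arithmetic(self):
        events = np.zeros(320, dtype=int)
        events[64] = events[160] = 1
        sess = EEGSession(np.zeros((2, 320)), 32, ["a", "b"], events, ["x", "y"])
        ep = make_epochs(sess, (-1.0, 1.0))
        assert ep.data.shape == (2, 2, 64)
        assert ep.labels == ["x", "y"]

    def test_full_protocol_epoch_count(self, default_errp_session):
        ep = make_epochs(default_errp_session, (-1.0, 1.0))
        assert ep.n_trials == 200
        assert ep.n_dropped == 0

    def test_boundary_event_dropped(self):
        events = np.zeros(1000, dtype=int)
        events[10] = events[600] = 1
        sess = EEGSession(np.zeros((1, 1000)), 256, ["a"], events, ["x", "y"])
        ep = make_epochs(sess, (-1.0, 1.0))
        assert ep.n_trials == 1 and ep.n_dropped == 1
        assert ep.labels == ["y"]

    def test_epoch_plus_dropped_equals_events(self, small_errp_session):
        ep = make_epochs(small_errp_session, (-1.0, 1.0))
        assert ep.n_trials + ep.n_dropped == len(small_errp_session.event_onsets())


def _brute_force_welch(x, fs, nperseg, noverlap):
    """Mean of individually computed Hann-windowed, demeaned periodograms."""
    win = sps.get_window("hann", nperseg)
    step = nperseg - noverlap
    scale = 1.0 / (fs * (win ** 2).sum())
    periodograms = []
    for start in range(0, len(x) - nperseg + 1, step):
        seg = x[start:start + nperseg]
        seg = (seg - seg.mean()) * win
        spec = np.abs(np.fft.rfft(seg)) ** 2 * scale
        spec[1:] *= 2
        if nperseg % 2 == 0:
            spec[-1] /= 2
        periodograms.append(spec)
    return np.mean(periodograms, axis=0)


class TestWelchPSD:
    def test_tone_concentration(self):
        # 2 s segments: the Hann main lobe stays strictly inside [9, 11] Hz
        t = np.arange(5 * 256) / 256
        psd = welch_psd(np.sin(2 * np.pi * 10 * t), 256, segment_seconds=2.0)
        total = np.trapezoid(psd.power, psd.freqs)
        band = band_power(psd, (9.0, 11.0))
        assert band / total >= 0.90

    def test_zero_signal(self):
        psd = welch_psd(np.zeros(1024), 256)
        assert np.allclose(psd.power, 0)

    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(256 * 60)
        psd = welch_psd(x, 256)
        assert 0.9 <= np.trapezoid(psd.power, psd.freqs) <= 1.1

    def test_matches_brute_force_periodogram_mean(self, rng):
        x = rng.standard_normal(1280)
        psd = welch_psd(x, 256, segment_seconds=1.0, overlap_fraction=0.5)
        oracle = _brute_force_welch(x, 256, 256, 128)
        assert np.max(np.abs(psd.power - oracle)) < 1e-10

    def test_segment_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), 256, segment_seconds=1.0)


class TestBandPower:
    flat = PSD(freqs=np.arange(0, 129.0), power=np.ones(129), resolution=1.0)

    @pytest.mark.parametrize("band,expected", [((8.0, 13.0), 5.0), ((4.0, 8.0), 4.0)])
    def test_flat_density_width(self, band, expected):
        assert band_power(self.flat, band) == pytest.approx(expected, abs=1e-12)

    def test_tone_dominates_its_band(self):
        t = np.arange(5 * 256) / 256
        psd = welch_psd(np.sin(2 * np.pi * 10 * t), 256)
        assert band_power(psd, (8.0, 13.0)) > 10 * band_power(psd, (13.0, 30.0))

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            band_power(self.flat, (8.0, 8.0))

    @settings(deadline=None, max_examples=25)
    @given(split=st.floats(min_value=4.5, max_value=29.5))
    def test_contiguous_bands_sum_to_union(self, split):
        rng = np.random.default_rng(7)
        psd = PSD(freqs=np.arange(0, 129.0), power=rng.random(129), resolution=1.0)
        left = band_power(psd, (4.0, split))
        right = band_power(psd, (split, 30.0))
        union = band_power(psd, (4.0, 30.0))
        assert left + right == pytest.approx(union, rel=1e-9)
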