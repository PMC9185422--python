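"""SNR closed forms and RR-interval/heart-rate arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steerecg.core import BeatAnnotation, Recording
from steerecg.metrics import (
    SnrSpec,
    fundamental_from_annotation,
    hr_series,
    snr_db,
)

FS = 500.0
FUND = 1.2  # Hz


def shaped_noise(power, duration=60.0, fs=FS, fundamental=FUND, spec=None, seed=0):
    """In-band noise with given total power, avoiding the harmonic bands.

    Built in the frequency domain with random phases on 0.5-25 Hz bins
    outside the fundamental's harmonic windows, so P_signal and P_noise
    separate exactly.
    """
    spec = spec or SnrSpec()
    n = int(duration * fs)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    mask = (freqs >= 0.6) & (freqs <= 24.9)
    for k in range(1, spec.harmonics + 1):
        mask &= np.abs(freqs - k * fundamental) > 2 * spec.band_halfwidth
    rng = np.random.default_rng(seed)
    spectrum = np.zeros(len(freqs), dtype=complex)
    spectrum[mask] = np.exp(2j * np.pi * rng.random(mask.sum()))
    x = np.fft.irfft(spectrum, n)
    x *= np.sqrt(power / np.mean(x**2))
    return x


class TestSnr:
    def test_equal_band_powers_give_zero_db(self):
        n = int(60 * FS)
        t = np.arange(n) / FS
        sig = np.sin(2 * np.pi * FUND * t)  # power 0.5
        noise = shaped_noise(0.5)
        rec = Recording(sig + noise, FS, "wheel", "city", "A")
        out = snr_db(rec, FUND)
        assert out.mean_db == pytest.approx(0.0, abs=0.5)

    def test_tenfold_noise_amplitude_costs_20_db(self):
        n = int(60 * FS)
        t = np.arange(n) / FS
        sig = np.sin(2 * np.pi * FUND * t)
        noise = shaped_noise(0.5)
        s1 = snr_db(Recording(sig + noise, FS, "wheel", "city", "A"), FUND).mean_db
        s2 = snr_db(Recording(sig + 10 * noise, FS, "wheel", "city", "A"), FUND).mean_db
        assert s1 - s2 == pytest.approx(20.0, abs=1.0)

    def test_amplitude_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * FUND * t) + 0.5 * rng.normal(size=len(t))
        a = snr_db(Recording(x, FS, "wheel", "city", "A"), FUND).mean_db
        b = snr_db(Recording(7.3 * x, FS, "wheel", "city", "A"), FUND).mean_db
        assert a == pytest.approx(b, abs=1e-9)

    def test_pure_fundamental_clamps_high(self):
        t = np.arange(int(60 * FS)) / FS
        rec = Recording(np.sin(2 * np.pi * 1.0 * t), FS, "wheel", "city", "A")
        with pytest.warns(UserWarning, match="clamped"):
            out = snr_db(rec, 1.0)
        assert out.mean_db == pytest.approx(99.0)

    def test_recording_value_is_mean_of_segments(self):
        rng = np.random.default_rng(5)
        t = np.arange(int(180 * FS)) / FS
        x = np.sin(2 * np.pi * FUND * t) + 0.4 * rng.normal(size=len(t))
        out = snr_db(Recording(x, FS, "wheel", "city", "A"), FUND)
        assert len(out.segment_snr_db) == 3
        assert out.mean_db == pytest.approx(np.mean(out.segment_snr_db))

    def test_segment_longer_than_recording_rejected(self):
        rec = Recording(np.zeros(int(30 * FS)), FS, "wheel", "city", "A")
        with pytest.raises(ValueError, match="segment"):
            snr_db(rec, 1.0, SnrSpec(segment=60.0))


class TestHrSeries:
    def test_one_second_intervals(self):
        ann = BeatAnnotation(np.array([0, 500, 1000]), "truth", FS)
        hs = hr_series(ann)
        np.testing.assert_allclose(hs.rri, [1.0, 1.0])
        np.testing.assert_allclose(hs.hr, [60.0, 60.0])
        np.testing.assert_allclose(hs.times, [1.0, 2.0])

    def test_half_second_interval_is_120_bpm(self):
        ann = BeatAnnotation(np.array([0, 250]), "truth", FS)
        assert hr_series(ann).hr[0] == pytest.approx(120.0)

    def test_fewer_than_two_peaks_empty(self):
        assert len(hr_series(BeatAnnotation(np.array([100]), "truth", FS))) == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=2000), min_size=2, max_size=50)
    )
    def test_hr_times_rri_identity(self, gaps):
        peaks = np.cumsum(np.asarray(gaps, dtype=np.int64))
        hs = hr_series(BeatAnnotation(peaks, "truth", FS))
        np.testing.assert_allclose(hs.hr * hs.rri, 60.0, atol=1e-12)

    def test_translation_equivariance(self):
        peaks = np.array([100, 600, 1100, 1700])
        a = hr_series(BeatAnnotation(peaks, "truth", FS))
        b = hr_series(BeatAnnotation(peaks + 250, "truth", FS))
        np.testing.assert_allclose(b.rri, a.rri)
        np.testing.assert_allclose(b.times, a.times + 0.5)


def test_fundamental_tracks_reference_hr():
    peaks = np.arange(0, int(120 * FS), int(FS))  # 60 bpm for 2 min
    ann = BeatAnnotation(peaks, "consensus", FS)
    fund = fundamental_from_annotation(ann, 60.0, 120.0)
    np.testing.assert_allclose(fund, 1.0, atol=1e-3)
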