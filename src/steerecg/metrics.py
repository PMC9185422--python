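"""Signal quality and heart-rate metrics.

SNR of the wheel channel is defined against the heart rhythm visible in
the chest reference: the signal power is the periodogram power inside
narrow bands around the cardiac fundamental (mean reference HR / 60)
and its first few harmonics, and the noise power is the remaining power
inside the 0.5–25 Hz analysis band.  SNR = 10 log10(P_signal / P_noise)
dB, computed per non-overlapping segment (default 60 s) and averaged on
the dB scale for the recording-level figure.

Heart rate derives from the RR intervals of an annotation:
``rri[i] = (peaks[i+1] - peaks[i]) / fs`` and ``hr = 60 / rri`` bpm,
time-stamped at the second beat of each pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from steerecg.core import BeatAnnotation, Recording

SNR_CLAMP_DB = 99.0
_ANALYSIS_BAND = (0.5, 25.0)


@dataclass
class SnrSpec:
    """Harmonic-band SNR parameters.

    ``harmonics`` fundamental multiples counted as signal;
    ``band_halfwidth`` half-width in Hz of each harmonic band;
    ``segment`` segment length in seconds.
    """

    harmonics: int = 5
    band_halfwidth: float = 0.2
    segment: float = 60.0

    def __post_init__(self) -> None:
        if self.harmonics < 1:
            raise ValueError(f"harmonics must be >= 1, got {self.harmonics}")
        if self.band_halfwidth <= 0:
            raise ValueError(f"band_halfwidth must be positive, got {self.band_halfwidth}")
        if self.segment <= 0:
            raise ValueError(f"segment must be positive, got {self.segment}")


@dataclass
class SnrResult:
    """Per-segment and recording-level SNR in dB."""

    segment_starts_s: np.ndarray
    segment_snr_db: np.ndarray

    @property
    def mean_db(self) -> float:
        return float(np.mean(self.segment_snr_db))


def _segment_snr(x: np.ndarray, fs: float, fundamental: float, spec: SnrSpec) -> float:
    freqs, psd = sps.periodogram(x, fs=fs)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    in_band = (freqs >= _ANALYSIS_BAND[0]) & (freqs <= _ANALYSIS_BAND[1])
    p_total = float(np.sum(psd[in_band]) * df)

    sig_mask = np.zeros_like(in_band)
    for k in range(1, spec.harmonics + 1):
        f0 = k * fundamental
        sig_mask |= np.abs(freqs - f0) <= spec.band_halfwidth
    sig_mask &= in_band
    p_signal = float(np.sum(psd[sig_mask]) * df)
    p_noise = p_total - p_signal
    if p_noise <= 0.0:
        warnings.warn("noise power is non-positive; SNR clamped to +99 dB")
        return SNR_CLAMP_DB
    if p_signal <= 0.0:
        return -SNR_CLAMP_DB
    return float(10.0 * np.log10(p_signal / p_noise))


def snr_db(
    wheel: Recording,
    ref_hr_fundamental: float | np.ndarray,
    spec: SnrSpec | None = None,
) -> SnrResult:
    """Harmonic-band SNR of the wheel channel, per segment.

    ``ref_hr_fundamental`` is the cardiac fundamental in Hz (mean
    reference-channel HR over the segment divided by 60), either one
    value for the whole recording or one per segment.
    """
    spec = spec or SnrSpec()
    seg_len = int(spec.segment * wheel.fs)
    if seg_len > len(wheel.samples):
        raise ValueError(
            f"segment of {spec.segment} s exceeds recording length {wheel.duration:.1f} s"
        )
    n_seg = len(wheel.samples) // seg_len
    fund = np.broadcast_to(np.atleast_1d(ref_hr_fundamental), (n_seg,))
    if np.any(fund <= 0):
        raise ValueError("fundamental frequency must be positive")

    starts, values = [], []
    for s in range(n_seg):
        lo = s * seg_len
        x = wheel.samples[lo : lo + seg_len]
        values.append(_segment_snr(x, wheel.fs, float(fund[s]), spec))
        starts.append(lo / wheel.fs)
    return SnrResult(np.asarray(starts), np.asarray(values))


def fundamental_from_annotation(
    ann: BeatAnnotation, segment_s: float, duration_s: float
) -> np.ndarray:
    """Per-segment cardiac fundamental (Hz) from a reference annotation.

    Each segment's fundamental is the mean heart rate of the beats whose
    RR interval ends inside the segment, divided by 60.  Segments
    without beats inherit the recording-wide mean.
    """
    hs = hr_series(ann)
    n_seg = int(duration_s // segment_s)
    if len(hs.hr) == 0:
        raise ValueError("annotation has fewer than two peaks; no heart rate defined")
    overall = float(np.mean(hs.hr)) / 60.0
    fund = np.full(n_seg, overall)
    seg_idx = (hs.times // segment_s).astype(int)
    for s in range(n_seg):
        sel = seg_idx == s
        if np.any(sel):
            fund[s] = float(np.mean(hs.hr[sel])) / 60.0
    return fund


@dataclass
class HrSeries:
    """RR intervals and heart rate, stamped at the second beat of each pair."""

    times: np.ndarray
    rri: np.ndarray
    hr: np.ndarray

    def __len__(self) -> int:
        return len(self.rri)


def hr_series(ann: BeatAnnotation) -> HrSeries:
    """RR intervals (s) and heart rate (bpm) from an annotation.

    With fewer than two peaks the series is empty.
    """
    if len(ann.peaks) < 2:
        empty = np.array([])
        return HrSeries(empty, empty, empty)
    rri = np.diff(ann.peaks) / ann.fs
    times = ann.peaks[1:] / ann.fs
    return HrSeries(times, rri, 60.0 / rri)
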