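"""Shared domain containers: recordings and beat annotations.

Conventions used throughout the package: waveforms are in millivolts,
sample indices are 0-based, intervals are half-open ``[start, end)`` in
samples, and time at API boundaries is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("reference", "wheel")
SCENARIOS = ("rest", "city", "highway", "rural")


@dataclass
class Recording:
    """One channel of one scenario of one subject's session.

    Parameters
    ----------
    samples:
        Waveform in millivolts.
    fs:
        Sampling rate in Hz (both channels of the study hardware run at
        500 Hz).
    channel:
        ``"reference"`` (chest lead, treated as ground truth) or
        ``"wheel"`` (steering-wheel electrodes).
    scenario:
        One of ``rest``, ``city``, ``highway``, ``rural``.
    subject_id:
        Free-form subject identifier.
    """

    samples: np.ndarray
    fs: float = 500.0
    channel: str = "reference"
    scenario: str = "rest"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"scenario must be one of {SCENARIOS}, got {self.scenario!r}"
            )

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self.samples)) / self.fs


@dataclass
class BeatAnnotation:
    """Ordered R-wave positions with provenance.

    ``peaks`` holds strictly increasing 0-based sample indices;
    ``provenance`` records where they came from (``"truth"``, a detector
    name, or ``"consensus"``).
    """

    peaks: np.ndarray
    provenance: str = "truth"
    fs: float = 500.0

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=np.int64)
        if self.peaks.ndim != 1:
            raise ValueError("peaks must be a 1-D array")
        if len(self.peaks) > 1 and not np.all(np.diff(self.peaks) > 0):
            raise ValueError("peak indices must be strictly increasing")
        if len(self.peaks) and self.peaks[0] < 0:
            raise ValueError("peak indices must be non-negative")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.peaks)

    def times(self) -> np.ndarray:
        """Peak times in seconds."""
        return self.peaks / self.fs


@dataclass
class Interval:
    """Half-open sample interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def clip_intervals(intervals: list[Interval], n: int) -> list[Interval]:
    """Clip intervals to ``[0, n)``, dropping empty ones, sorted by start."""
    out = []
    for iv in intervals:
        s, e = max(iv.start, 0), min(iv.end, n)
        if e > s:
            out.append(Interval(s, e))
    return sorted(out, key=lambda iv: iv.start)
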