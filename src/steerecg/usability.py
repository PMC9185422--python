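"""Beat-level reliability rules and usable-time bookkeeping.

A wheel-channel beat is unreliable if any of three rules fires:

* RRI jump — the RR interval changed by more than 0.08 s from the
  previous beat (ectopy-or-artifact criterion);
* HR tube — its instantaneous heart rate strays more than a tube
  half-width (default 10 bpm) from the median reference heart rate;
* amplitude — its R amplitude exceeds a multiple (default 3x) of the
  median R amplitude, catching motion-artifact spikes misread as beats.

The chest reference is trusted: when classifying the reference channel
itself the RRI-jump rule is skipped.  The 60–100 bpm normal range is
used only as a sanity check on the reference median (a warning, not a
rejection).

Beat labels are aggregated to minutes by partitioning the recording
into non-overlapping windows (default 60 s); a window counts as usable
when it contains at least one beat and at least 90 % of its beats are
reliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from steerecg.metrics import HrSeries

RULE_NONE = ""
RULE_RRI_JUMP = "rri_jump"
RULE_HR_TUBE = "hr_tube"
RULE_AMPLITUDE = "amplitude"


@dataclass
class UsabilityRules:
    """Thresholds of the reliability rules; see module docstring."""

    rri_jump_max: float = 0.08
    hr_tube_halfwidth: float = 10.0
    amp_tube_factor: float = 3.0
    hr_normal_low: float = 60.0
    hr_normal_high: float = 100.0
    window: float = 60.0
    window_reliable_frac: float = 0.9

    def __post_init__(self) -> None:
        for attr in (
            "rri_jump_max",
            "hr_tube_halfwidth",
            "amp_tube_factor",
            "hr_normal_low",
            "hr_normal_high",
            "window",
            "window_reliable_frac",
        ):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive, got {getattr(self, attr)}")
        if self.hr_normal_low >= self.hr_normal_high:
            raise ValueError("hr_normal_low must be below hr_normal_high")


@dataclass
class BeatLabels:
    """Per-beat reliability verdicts.

    ``reliable[i]`` refers to the beat at ``times[i]``; ``rule_fired``
    names the first rule that flagged it (empty string when reliable).
    """

    times: np.ndarray
    reliable: np.ndarray
    rule_fired: list[str]

    def __len__(self) -> int:
        return len(self.times)


def classify_beats(
    wheel_hr: HrSeries,
    ref_hr: HrSeries,
    wheel_amp: np.ndarray | None = None,
    rules: UsabilityRules | None = None,
    is_reference: bool = False,
) -> BeatLabels:
    """Apply the reliability rules to one channel's heart-rate series.

    ``wheel_amp`` gives the R amplitude of the beat ending each RR
    interval (same length as ``wheel_hr``); omit it to skip the
    amplitude rule.  With ``is_reference`` the RRI-jump rule is skipped
    — the chest lead is trusted for rhythm.
    """
    rules = rules or UsabilityRules()
    n = len(wheel_hr)
    if n == 0:
        raise ValueError("heart-rate series is empty")
    if len(ref_hr) == 0:
        raise ValueError("reference heart-rate series is empty")

    ref_median = float(np.median(ref_hr.hr))
    if not rules.hr_normal_low <= ref_median <= rules.hr_normal_high:
        warnings.warn(
            f"median reference HR {ref_median:.1f} bpm is outside the normal "
            f"{rules.hr_normal_low:.0f}-{rules.hr_normal_high:.0f} bpm range"
        )

    reliable = np.ones(n, dtype=bool)
    fired = [RULE_NONE] * n

    if not is_reference:
        jumps = np.abs(np.diff(wheel_hr.rri))
        for i in np.nonzero(jumps > rules.rri_jump_max)[0]:
            reliable[i + 1] = False
            fired[i + 1] = RULE_RRI_JUMP

    off_tube = np.abs(wheel_hr.hr - ref_median) > rules.hr_tube_halfwidth
    for i in np.nonzero(off_tube)[0]:
        if reliable[i]:
            reliable[i] = False
            fired[i] = RULE_HR_TUBE

    if wheel_amp is not None:
        amp = np.asarray(wheel_amp, dtype=float)
        if len(amp) != n:
            raise ValueError(
                f"wheel_amp length {len(amp)} does not match series length {n}"
            )
        med_amp = float(np.median(amp))
        for i in np.nonzero(amp > rules.amp_tube_factor * med_amp)[0]:
            if reliable[i]:
                reliable[i] = False
                fired[i] = RULE_AMPLITUDE

    return BeatLabels(np.asarray(wheel_hr.times, dtype=float), reliable, fired)


def usable_time(
    labels: BeatLabels,
    total_duration: float,
    window: float = 60.0,
    window_reliable_frac: float = 0.9,
) -> tuple[float, float]:
    """Aggregate beat labels into usable minutes and usable fraction.

    The recording is split into non-overlapping windows; a window is
    usable iff it holds at least one beat and its reliable-beat fraction
    is at least ``window_reliable_frac``.  Returns
    ``(usable_minutes, usable_fraction)`` where the fraction is over the
    total duration.
    """
    if total_duration <= 0:
        raise ValueError(f"total_duration must be positive, got {total_duration}")
    if np.any(labels.times > total_duration):
        raise ValueError("beat timestamps exceed total_duration")
    n_windows = int(np.ceil(total_duration / window))
    idx = (labels.times // window).astype(int)
    # The last window may be shorter than `window`; count its real span.
    usable_minutes = 0.0
    for wi in range(n_windows):
        sel = idx == wi
        if not np.any(sel) or float(np.mean(labels.reliable[sel])) < window_reliable_frac:
            continue
        span = min(window, total_duration - wi * window)
        usable_minutes += span / 60.0
    usable_fraction = usable_minutes / (total_duration / 60.0)
    return usable_minutes, usable_fraction
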