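"""Band-pass conditioning of raw ECG channels.

The analysis band is 0.5–25 Hz: the lower cutoff removes baseline wander
(respiration, contact drift), the upper removes broadband and mains
noise while keeping the QRS energy.  A zero-phase (forward–backward)
Butterworth is used by default so R-peak timing — which the RR-interval
usability rule depends on — is not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from steerecg.core import Recording

_EDGE_PAD_SECONDS = 5.0


@dataclass
class FilterSpec:
    """Butterworth band-pass specification.

    ``order`` is the analog prototype order; with ``zero_phase`` the
    filter is applied forward and backward, doubling the effective order
    and cancelling group delay.
    """

    low_cut: float = 0.5
    high_cut: float = 25.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.low_cut <= 0:
            raise ValueError(f"low_cut must be positive, got {self.low_cut}")
        if self.high_cut <= self.low_cut:
            raise ValueError(
                f"high_cut ({self.high_cut}) must exceed low_cut ({self.low_cut})"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")


def bandpass_array(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Band-pass a raw array; see :func:`bandpass` for the semantics."""
    spec = spec or FilterSpec()
    if spec.high_cut >= fs / 2:
        raise ValueError(
            f"high_cut {spec.high_cut} Hz must be below the Nyquist frequency {fs / 2} Hz"
        )
    sos = signal.butter(
        spec.order, [spec.low_cut, spec.high_cut], btype="bandpass", fs=fs, output="sos"
    )
    # Reflect-pad so filter transients live in discarded margins.
    pad = min(int(_EDGE_PAD_SECONDS * fs), max(len(x) - 1, 0))
    xp = np.pad(x, pad, mode="reflect") if pad > 0 else x
    if spec.zero_phase:
        y = signal.sosfiltfilt(sos, xp, padlen=0)
    else:
        y = signal.sosfilt(sos, xp)
    return y[pad : pad + len(x)] if pad > 0 else y


def bandpass(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Apply the Butterworth band-pass to a recording.

    Output length equals input length; edges are reflect-padded by 5 s
    before filtering and trimmed afterwards.
    """
    filtered = bandpass_array(rec.samples, rec.fs, spec)
    return Recording(filtered, rec.fs, rec.channel, rec.scenario, rec.subject_id)
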