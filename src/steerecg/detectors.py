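"""Classical R-peak detectors used as independent raters for fusion.

Three heterogeneous detectors are implemented behind one interface:

* :func:`detect_pan_tompkins` — band-pass, derivative, squaring,
  moving-window integration and adaptive dual thresholds with
  search-back;
* :func:`detect_derivative` — squared first derivative against an
  adaptive fraction-of-running-maximum threshold;
* :func:`detect_shannon_energy` — Shannon-energy envelope of the
  normalized differentiated signal with envelope peak picking.

Each detector defines its own front-end filtering and therefore runs on
the raw channel.  All detectors enforce a refractory period (default
200 ms) and refine detections to the local maximum of their band-passed
signal within +/-50 ms, breaking amplitude ties toward the earliest
index.  Additional detectors plug in through :class:`DetectorBank`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage, signal

from steerecg.core import BeatAnnotation, Recording
from steerecg.preprocess import FilterSpec, bandpass_array

logger = logging.getLogger(__name__)

REFRACTORY_S = 0.2
REFINE_HALFWIDTH_S = 0.05
_MIN_DURATION_S = 2.0

DetectorFunc = Callable[[Recording], BeatAnnotation]


def _too_short(rec: Recording, name: str) -> bool:
    if rec.duration < _MIN_DURATION_S:
        logger.warning(
            "%s: recording of %.2f s is shorter than %.1f s; returning no beats",
            name,
            rec.duration,
            _MIN_DURATION_S,
        )
        return True
    return False


def _refine_to_local_max(
    sig: np.ndarray, peaks: np.ndarray, fs: float, halfwidth_s: float = REFINE_HALFWIDTH_S
) -> np.ndarray:
    """Snap each peak to the maximum of ``sig`` within +/-halfwidth.

    ``np.argmax`` returns the first maximum, so equal-height ties break
    toward the earliest index.
    """
    hw = int(round(halfwidth_s * fs))
    refined = np.empty_like(peaks)
    for i, p in enumerate(peaks):
        lo = max(p - hw, 0)
        hi = min(p + hw + 1, len(sig))
        refined[i] = lo + int(np.argmax(sig[lo:hi]))
    return refined


def _enforce_refractory(
    peaks: np.ndarray, heights: np.ndarray, refractory_samples: int
) -> np.ndarray:
    """Deduplicate and thin peaks closer than the refractory period.

    When two detections collide, the taller one survives.
    """
    if len(peaks) == 0:
        return peaks
    order = np.argsort(peaks, kind="stable")
    peaks, heights = peaks[order], heights[order]
    kept_p: list[int] = []
    kept_h: list[float] = []
    for p, h in zip(peaks, heights):
        if kept_p and p - kept_p[-1] < refractory_samples:
            if h > kept_h[-1]:
                kept_p[-1], kept_h[-1] = int(p), float(h)
        else:
            kept_p.append(int(p))
            kept_h.append(float(h))
    return np.asarray(kept_p, dtype=np.int64)


def _finalize(
    rec: Recording, filtered: np.ndarray, raw_peaks: np.ndarray, name: str
) -> BeatAnnotation:
    refractory = int(REFRACTORY_S * rec.fs)
    refined = _refine_to_local_max(filtered, raw_peaks, rec.fs)
    final = _enforce_refractory(refined, filtered[refined], refractory)
    return BeatAnnotation(final, provenance=name, fs=rec.fs)


def detect_pan_tompkins(rec: Recording) -> BeatAnnotation:
    """Pan–Tompkins detector.

    Pipeline: 5–15 Hz band-pass, derivative, squaring, 150 ms
    moving-window integration, then adaptive dual thresholds over the
    integrated waveform with running signal/noise peak estimates and a
    search-back pass at half threshold when more than 1.66 mean RR
    elapses without a detection.
    """
    if _too_short(rec, "pan_tompkins"):
        return BeatAnnotation(np.array([], dtype=np.int64), "pan_tompkins", rec.fs)
    fs = rec.fs
    band = bandpass_array(rec.samples, fs, FilterSpec(5.0, 15.0, order=2))
    deriv = np.gradient(band)
    squared = deriv**2
    win = max(int(0.150 * fs), 1)
    mwi = ndimage.uniform_filter1d(squared, win, mode="nearest")

    refractory = int(REFRACTORY_S * fs)
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        return BeatAnnotation(np.array([], dtype=np.int64), "pan_tompkins", fs)

    init = mwi[: int(2.0 * fs)]
    spki = 0.25 * float(init.max())
    npki = 0.5 * float(init.mean())
    detections: list[int] = []
    rr_history: list[int] = []
    last_checked = 0

    for j, p in enumerate(cand):
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[p] > thr1:
            detections.append(int(p))
            spki = 0.125 * mwi[p] + 0.875 * spki
            if len(detections) >= 2:
                rr_history.append(detections[-1] - detections[-2])
                rr_history = rr_history[-8:]
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
            # Search-back: if a long gap has opened, re-admit the tallest
            # rejected candidate above half threshold.
            if detections and rr_history:
                mean_rr = float(np.mean(rr_history))
                if p - detections[-1] > 1.66 * mean_rr:
                    gap = [
                        c
                        for c in cand[last_checked : j + 1]
                        if detections[-1] + refractory <= c <= p
                        and mwi[c] > 0.5 * thr1
                    ]
                    if gap:
                        best = int(max(gap, key=lambda c: mwi[c]))
                        detections.append(best)
                        spki = 0.25 * mwi[best] + 0.75 * spki
                        rr_history.append(detections[-1] - detections[-2])
                        rr_history = rr_history[-8:]
        last_checked = j

    raw = np.asarray(sorted(set(detections)), dtype=np.int64)
    return _finalize(rec, band, raw, "pan_tompkins")


def detect_derivative(rec: Recording) -> BeatAnnotation:
    """Squared-derivative detector with an adaptive running threshold.

    The squared first derivative of the 8–20 Hz filtered signal is
    compared against 20 % of its running maximum over a centered 2 s
    window; candidates closer than the refractory period are thinned.
    """
    if _too_short(rec, "derivative"):
        return BeatAnnotation(np.array([], dtype=np.int64), "derivative", rec.fs)
    fs = rec.fs
    band = bandpass_array(rec.samples, fs, FilterSpec(8.0, 20.0, order=2))
    energy = np.gradient(band) ** 2
    energy = ndimage.uniform_filter1d(energy, max(int(0.05 * fs), 1), mode="nearest")

    run_max = ndimage.maximum_filter1d(energy, int(2.0 * fs), mode="nearest")
    refractory = int(REFRACTORY_S * fs)
    cand, _ = signal.find_peaks(energy, distance=refractory)
    cand = cand[energy[cand] >= 0.2 * run_max[cand]]
    return _finalize(rec, band, cand.astype(np.int64), "derivative")


def detect_shannon_energy(rec: Recording) -> BeatAnnotation:
    """Shannon-energy envelope detector.

    The differentiated, amplitude-normalized signal d is mapped to
    ``-d**2 * log(d**2)``, which flattens amplitude variation while
    emphasizing the steep QRS slopes; the envelope is smoothed over
    120 ms and peaks above 10 % of the running envelope maximum are kept.
    """
    if _too_short(rec, "shannon_energy"):
        return BeatAnnotation(np.array([], dtype=np.int64), "shannon_energy", rec.fs)
    fs = rec.fs
    band = bandpass_array(rec.samples, fs, FilterSpec(5.0, 20.0, order=2))
    d = np.gradient(band)
    max_abs = float(np.max(np.abs(d)))
    if max_abs == 0.0:
        return BeatAnnotation(np.array([], dtype=np.int64), "shannon_energy", fs)
    dn = d / max_abs
    se = -(dn**2) * np.log(dn**2 + 1e-12)
    env = ndimage.uniform_filter1d(se, max(int(0.120 * fs), 1), mode="nearest")

    run_max = ndimage.maximum_filter1d(env, int(2.0 * fs), mode="nearest")
    refractory = int(REFRACTORY_S * fs)
    cand, _ = signal.find_peaks(env, distance=refractory)
    cand = cand[env[cand] >= 0.1 * run_max[cand]]
    return _finalize(rec, band, cand.astype(np.int64), "shannon_energy")


@dataclass
class DetectorBank:
    """Ordered bank of named detectors feeding the fusion stage."""

    detectors: list[tuple[str, DetectorFunc]]
    refractory: float = REFRACTORY_S

    def __post_init__(self) -> None:
        names = [name for name, _ in self.detectors]
        if len(set(names)) != len(names):
            raise ValueError(f"detector names must be unique, got {names}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.detectors]


def default_bank() -> DetectorBank:
    """The three built-in detectors in canonical order."""
    return DetectorBank(
        [
            ("pan_tompkins", detect_pan_tompkins),
            ("derivative", detect_derivative),
            ("shannon_energy", detect_shannon_energy),
        ]
    )


def run_bank(bank: DetectorBank, rec: Recording) -> list[BeatAnnotation]:
    """Run every detector; a failing detector yields an empty annotation.

    Individual detector exceptions are logged, never propagated, so one
    broken rater cannot take down the fusion pipeline.
    """
    if not bank.detectors:
        raise ValueError("detector bank is empty")
    annotations = []
    for name, fn in bank.detectors:
        try:
            ann = fn(rec)
        except Exception:
            logger.exception("detector %r failed; substituting empty annotation", name)
            ann = BeatAnnotation(np.array([], dtype=np.int64), name, rec.fs)
        annotations.append(ann)
    return annotations


def match_to_truth(
    detected: BeatAnnotation, truth: np.ndarray, tolerance_s: float = 0.05
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to truth peaks.

    Returns ``(true_positives, false_positives, false_negatives)`` at
    the given time tolerance.
    """
    tol = int(round(tolerance_s * detected.fs))
    truth = np.asarray(truth, dtype=np.int64)
    used = np.zeros(len(truth), dtype=bool)
    tp = 0
    for p in detected.peaks:
        idx = np.searchsorted(truth, p)
        best, best_d = -1, tol + 1
        for j in (idx - 1, idx):
            if 0 <= j < len(truth) and not used[j]:
                d = abs(int(truth[j]) - int(p))
                if d < best_d:
                    best, best_d = j, d
        if best >= 0 and best_d <= tol:
            used[best] = True
            tp += 1
    fp = len(detected.peaks) - tp
    fn = len(truth) - tp
    return tp, fp, fn


def f1_score(detected: BeatAnnotation, truth: np.ndarray, tolerance_s: float = 0.05) -> float:
    """F1 of a detection list against truth peaks at a time tolerance."""
    tp, fp, fn = match_to_truth(detected, truth, tolerance_s)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0
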