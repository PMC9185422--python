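"""End-to-end analysis: detect, fuse, score and classify a session.

For each scenario of a session the pipeline

1. runs the detector bank on the chest reference, fuses with STAPLE and
   snap-refines the consensus — this is the rhythm ground truth;
2. does the same on the wheel channel to obtain wheel-side beats;
3. computes the wheel channel's harmonic-band SNR against the reference
   heart rate;
4. applies the reliability rules to the wheel beats (RRI jump, median-HR
   tube, amplitude cap) and aggregates usable minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from steerecg.core import BeatAnnotation, Recording
from steerecg.detectors import DetectorBank, default_bank, run_bank
from steerecg.metrics import SnrResult, SnrSpec, fundamental_from_annotation, hr_series, snr_db
from steerecg.preprocess import FilterSpec, bandpass_array
from steerecg.staple import StapleResult, build_decision_matrix, consensus_refine, staple_em
from steerecg.usability import BeatLabels, UsabilityRules, classify_beats, usable_time


@dataclass
class ScenarioAnalysis:
    """Everything computed for one scenario of one subject."""

    scenario: str
    subject_id: str
    ref_consensus: BeatAnnotation
    wheel_consensus: BeatAnnotation
    ref_staple: StapleResult
    wheel_staple: StapleResult
    snr: SnrResult
    labels: BeatLabels
    usable_minutes: float
    usable_fraction: float
    total_minutes: float


def fuse_channel(
    rec: Recording, bank: DetectorBank | None = None, tolerance: float = 0.05
) -> tuple[BeatAnnotation, StapleResult]:
    """Detector bank + STAPLE + snap refinement for one channel."""
    bank = bank or default_bank()
    annotations = run_bank(bank, rec)
    matrix = build_decision_matrix(annotations, rec.fs, tolerance)
    if matrix.n_candidates == 0:
        empty = BeatAnnotation(np.array([], dtype=np.int64), "consensus", rec.fs)
        result = StapleResult(
            consensus=empty,
            p=np.zeros(len(bank.names)),
            q=np.zeros(len(bank.names)),
            posteriors=np.array([]),
            candidates=np.array([], dtype=np.int64),
            detector_names=bank.names,
            iterations=0,
            converged=True,
        )
        return empty, result
    result = staple_em(matrix)
    consensus = consensus_refine(result, rec)
    return consensus, result


def analyze_scenario(
    ref: Recording,
    wheel: Recording,
    bank: DetectorBank | None = None,
    rules: UsabilityRules | None = None,
    snr_spec: SnrSpec | None = None,
) -> ScenarioAnalysis:
    """Full per-scenario analysis of a reference/wheel pair."""
    if ref.scenario != wheel.scenario:
        raise ValueError(f"channel scenarios differ: {ref.scenario} vs {wheel.scenario}")
    rules = rules or UsabilityRules()
    snr_spec = snr_spec or SnrSpec()

    ref_consensus, ref_res = fuse_channel(ref, bank)
    wheel_consensus, wheel_res = fuse_channel(wheel, bank)

    ref_hr = hr_series(ref_consensus)
    wheel_hr = hr_series(wheel_consensus)

    fund = fundamental_from_annotation(ref_consensus, snr_spec.segment, wheel.duration)
    snr = snr_db(wheel, fund, snr_spec)

    # R amplitude of the beat ending each RR interval, off the band-passed
    # wheel signal the consensus was refined on.
    filtered = bandpass_array(wheel.samples, wheel.fs, FilterSpec())
    amp = filtered[wheel_consensus.peaks[1:]] if len(wheel_consensus) > 1 else None

    labels = classify_beats(wheel_hr, ref_hr, amp, rules, is_reference=False)
    usable_min, usable_frac = usable_time(
        labels, wheel.duration, rules.window, rules.window_reliable_frac
    )
    return ScenarioAnalysis(
        scenario=ref.scenario,
        subject_id=ref.subject_id,
        ref_consensus=ref_consensus,
        wheel_consensus=wheel_consensus,
        ref_staple=ref_res,
        wheel_staple=wheel_res,
        snr=snr,
        labels=labels,
        usable_minutes=usable_min,
        usable_fraction=usable_frac,
        total_minutes=wheel.duration / 60.0,
    )


def analyze_session(
    recordings: list[Recording],
    bank: DetectorBank | None = None,
    rules: UsabilityRules | None = None,
    snr_spec: SnrSpec | None = None,
) -> dict[str, ScenarioAnalysis]:
    """Analyze every scenario present in a session's recordings."""
    by_key = {(r.scenario, r.channel): r for r in recordings}
    scenarios = sorted({sc for sc, _ in by_key})
    out: dict[str, ScenarioAnalysis] = {}
    for sc in scenarios:
        ref = by_key.get((sc, "reference"))
        wheel = by_key.get((sc, "wheel"))
        if ref is None or wheel is None:
            continue
        out[sc] = analyze_scenario(ref, wheel, bank, rules, snr_spec)
    return out
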