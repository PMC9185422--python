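# steerecg

Analysis pipeline for **steering-wheel electrocardiography**: how much of a
car journey yields a heart-rate recording you can trust when the ECG is
picked up through conductive electrodes on the steering wheel instead of
chest leads?

Wheel-contact ECG is attractive for in-vehicle health monitoring but
notoriously noisy — the signal is attenuated by the skin–electrode
coupling, contaminated by baseline wander and motion artifacts from
steering maneuvers, and vanishes entirely whenever a hand leaves the
wheel. This package implements the complete measurement-quality analysis
for such recordings and a synthetic dual-channel session generator, so the
whole chain can be exercised and validated without any data download.

## What it computes

* **R-peak consensus via STAPLE.** A bank of classical QRS detectors
  (Pan–Tompkins; squared-derivative with adaptive threshold;
  Shannon-energy envelope) act as independent raters. The STAPLE
  expectation–maximization algorithm treats each rater *j* as having
  unknown sensitivity *p&#8342;* and specificity *q&#8342;*, alternating

  - E-step: posterior that candidate *i* is a true beat,
    *w&#7522;* ∝ π Π&#8342; p&#8342;^{v&#7522;&#8342;}(1−p&#8342;)^{1−v&#7522;&#8342;},
    against (1−π) Π&#8342; (1−q&#8342;)^{v&#7522;&#8342;} q&#8342;^{1−v&#7522;&#8342;};
  - M-step: re-estimate (*p&#8342;*, *q&#8342;*) from the posteriors;

  and the consensus is the posterior ≥ 0.5 set — a weighted majority vote
  in which reliable detectors weigh more.
* **SNR of the wheel channel** (Eq. SNR = 10·log₁₀(P_signal/P_noise) dB):
  periodogram power in narrow bands around the cardiac fundamental
  (mean reference HR / 60) and its harmonics, versus the remaining
  0.5–25 Hz in-band power, per 60-s segment.
* **Usable time.** RR intervals (RRI) and heart rate HR = 60/RRI are
  derived from the consensus beats; a wheel beat is *unreliable* when its
  RRI changes by more than 0.08 s, its HR leaves a ±10 bpm tube around the
  median reference HR, or its amplitude exceeds 3× the median (the chest
  reference is exempt from the RRI rule). Windows with ≥ 90 % reliable
  beats accumulate usable minutes, aggregated per driving scenario
  (rest 5 min; city/highway/rural 15 min each; 19 subjects = 950 min).

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
their tables to `results/`:

```
python analysis/01_simulate_sessions.py    # demo cohort + truth sidecars
python analysis/02_detector_performance.py # rater F1 vs consensus F1
python analysis/03_staple_recovery.py      # EM parameter recovery
python analysis/04_study_usability.py      # full 19-subject study
```

`analysis/04_study_usability.py` prints (seed 7):

```
scenario  n_subjects  total_minutes  usable_minutes  usable_pct  mean_snr_db
    rest          19          95.00           57.00       60.00        -2.82
    city          19         285.00          112.00       39.30        -3.82
 highway          19         285.00          126.00       44.21        -3.67
   rural          19         285.00          134.00       47.02        -3.59

driving-time usable percentage (city/highway/rural mean): 43.51%
at 30 min of driving per day that is 13.05 usable min/day
```

Reading: of the 285 synthetic city-driving minutes, 112 (39.30 %) pass the
reliability rules; rest is calmer (60 %); the negative SNRs say the wheel
channel is noisier than the chest reference everywhere. The headline
driving percentage is the unweighted mean of the three driving scenarios'
rounded percentages.

`analysis/02_detector_performance.py` shows why fusion helps: on noisy
wheel recordings the individual raters reach F1 ≈ 0.66–0.91 against
ground truth while the STAPLE consensus sits at ≈ 0.92, at or above the
median rater.

## Layout

```
src/steerecg/     library: simulate, preprocess, detectors, staple,
                  metrics, usability, report, session_io, pipeline
analysis/         numbered narrative drivers (write results/ tables)
tests/            pytest suite (unit, property and end-to-end checks)
docs/methods.md   models, parameters, calibration and limitations
```
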