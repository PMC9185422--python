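# Methods

## Problem setting

Two simultaneous ECG channels are recorded at 500 Hz while a subject
drives: a chest lead (the *reference*, trusted for rhythm) and a
steering-wheel lead (the *wheel* channel, attenuated and artifact-laden).
A session consists of four scenarios — rest (5 min) and city, highway,
rural driving (15 min each) — and a study cohort has 19 subjects, i.e.
950 recorded minutes per channel. The analysis asks two questions: how
noisy is the wheel channel (SNR), and what fraction of the time does it
deliver a heart rate one can rely on (usable time)?

## Synthetic session generator

The generator exists so the full pipeline can be validated against exact
ground truth. It is a signal-level emulation, not a biophysical cardiac
model.

**Clean ECG.** Beats follow a renewal process: RR intervals are
60/`base_hr` seconds plus zero-mean Gaussian perturbations of standard
deviation 60·`hr_sd`/`base_hr`² (the first-order mapping of an `hr_sd`
bpm rate jitter onto the interval scale), floored at 0.25 s. An optional
AR(1) coefficient (`hr_ar1`) correlates successive perturbations at the
same marginal spread, shrinking beat-to-beat jumps the way real
heart-rate variability does; the default is 0 (independent). Each beat
contributes a PQRST template of five Gaussian bumps (P +0.15, Q −0.10,
R +1.00, S −0.20, T +0.35 relative amplitude at −200, −30, 0, +30,
+250 ms with 25/10/12/10/55 ms widths), scaled by the subject's R
amplitude. The R bump is centered exactly on a sample, so the returned
truth peaks are exact.

**Channels.** The reference is the clean signal plus mild white noise
(0.01 mV). The wheel channel is the clean signal times a per-subject
attenuation in (0, 1] plus scenario noise: white noise, sinusoidal
baseline wander, motion-artifact bursts (Poisson arrivals; each a
Gaussian-windowed 4–12 Hz oscillation of 1–2.5 mV, an order of magnitude
above the attenuated R wave) and dropout intervals (Poisson arrivals with
exponential lengths) inside which the cardiac component is removed —
contact loss leaves noise, not a flat line. All artifact and dropout
intervals are returned as half-open sample intervals.

**Cohort.** Subjects are drawn with base rates 58–88 bpm, beat-to-beat
variability 0.7–1.6 bpm, chest R amplitudes 0.8–1.2 mV and wheel
attenuation 0.35–0.7. The variability range corresponds to an RMSSD of
roughly 20–40 ms, typical of adults under light cognitive load. This
range matters: with independent Gaussian RR perturbations, a variability
of ~3 bpm at resting rates makes consecutive-interval jumps exceed the
0.08 s reliability threshold on over 10 % of perfectly clean beats, which
would say nothing about electrode quality — the rule is meant to catch
detection glitches and artifacts, not healthy HRV.

**Scenario profiles.** The default profiles order the scenarios
rest < city in event rates, with highway and rural comparable
(stop-and-go city traffic detaches hands from the wheel most often):
dropout rates 0.7/0.85/0.75/0.75 per minute (mean length 5 s), artifact
rates 1.1/1.4/1.2/1.3 per minute, wheel noise 0.04–0.05 mV. These
magnitudes are calibration choices — no per-scenario artifact statistics
are published for this setting — set so that the usability pipeline
classifies roughly 40–60 % of wheel time as reliable, the regime the
method is designed to discriminate in. The calibration used small pilot
cohorts whose seeds are disjoint from every seed used in the tests.

What the generator does *not* emulate: realistic QRS morphology changes,
ectopic beats, electrode impedance drift, mains interference, or the
coupling between steering maneuvers and simultaneous artifacts on both
channels. Passing tests therefore demonstrate the pipeline's correctness
and its behavior under controlled degradation, not field performance on
real wheel recordings.

## Preprocessing

Butterworth band-pass 0.5–25 Hz, order 4, applied forward–backward
(zero phase; effective order 8) so R-peak timing is untouched — the RRI
rule is sensitive to single-sample shifts. Edges are reflect-padded by
5 s and trimmed. Order and phase mode are configurable; only the cutoffs
are fixed by the analysis definition.

## Detector bank

Three heterogeneous detectors, each with its own front end on the raw
signal, all with a 200 ms refractory period and final refinement to the
local maximum of their band-passed signal within ±50 ms (ties break to
the earliest index):

* **Pan–Tompkins**: 5–15 Hz band-pass, derivative, squaring, 150 ms
  moving-window integration, adaptive dual thresholds with running
  signal/noise peak estimates and search-back at half threshold after
  1.66 mean-RR gaps.
* **Squared derivative**: 8–20 Hz band-pass, squared gradient smoothed
  over 50 ms, threshold 20 % of the running 2-s maximum.
* **Shannon energy**: 5–20 Hz band-pass, gradient normalized by its
  global maximum, −d²·log d² envelope smoothed over 120 ms, threshold
  10 % of the running 2-s maximum.

The bank is pluggable; additional raters only strengthen the consensus.
Fraction-of-running-maximum thresholds make the derivative and
Shannon-energy detectors fire on noise during dropouts (the running
maximum collapses to the noise floor). This is intentional realism: real
detectors do exactly that, and the downstream reliability rules are what
must catch it.

## STAPLE fusion

STAPLE operates on per-item binary decisions, while detectors emit point
events. The adaptation: pool all detections, single-linkage-cluster peaks
closer than 50 ms (half a typical QRS width), take the median member
index as the candidate representative, and set vote *v₍ᵢⱼ₎* = 1 iff rater
*j* has a member in cluster *i*. The EM then estimates each rater's
sensitivity/specificity and each candidate's posterior; consensus is
posterior ≥ 0.5, followed by snapping to the local maximum of the
0.5–25 Hz signal (collisions keep the higher posterior).

Numerical choices: prevalence prior = fraction of candidates with at
least half the votes, clamped to [0.05, 0.95] (configurable); (p, q)
initialized at 0.9 and clamped to [10⁻⁶, 1−10⁻⁶] so unanimous vote
columns cannot degenerate; E-step in log space; convergence when the
largest (p, q) change drops below 10⁻⁶ or after 100 sweeps. The
log-likelihood is non-decreasing by construction and asserted in tests.
Specificity is defined over candidate windows only — no background grid
of non-events is sampled. This keeps *q* interpretable ("stays silent
when other raters saw something spurious") but means *q* is not a
per-sample false-alarm rate; it is a documented limitation.

Fusion is applied to both channels: the reference consensus defines the
rhythm ground truth, and the wheel consensus supplies the wheel-side
heart-rate estimate the usability rules judge.

## SNR

Per non-overlapping 60-s segment: periodogram PSD of the wheel channel;
signal power = power within ±0.2 Hz of k·f₀ for k = 1…5, where f₀ is the
segment's mean reference heart rate divided by 60; noise power = the
remaining 0.5–25 Hz in-band power; SNR = 10·log₁₀(P_signal/P_noise).
The recording-level value is the arithmetic mean of the segment dB values
(not the dB of mean powers) — segments are weighted equally regardless of
their absolute power. Non-positive noise power clamps to +99 dB with a
warning. The harmonic-band partition (5 harmonics, ±0.2 Hz) is this
package's concrete definition of a quantity often left vague; both knobs
are configurable.

## Usability rules

Per wheel beat, evaluated on the consensus-derived HR series:

1. **RRI jump** — |ΔRRI| > 0.08 s between consecutive beats flags the
   later beat. Skipped entirely when classifying the reference channel.
2. **HR tube** — |HR − median(reference HR)| > 10 bpm.
3. **Amplitude** — R amplitude > 3× the median R amplitude.

Rules fire independently and the first one to fire is recorded per beat.
The 0.08 s threshold is part of the analysis definition; the tube
half-width (10 bpm) and the amplitude factor (3×) are this package's
defaults where the published description conflates the two criteria, and
both are configurable. The 60–100 bpm normal range is used only as a
sanity check on the reference median (warning, not rejection).

Minutes bookkeeping: 60-s windows; a window is usable iff it contains at
least one beat and ≥ 90 % of its beats are reliable. Windows without
beats (total dropout) are unusable by construction. Usable fraction is
usable minutes over total minutes.

## Reporting conventions

Scenario usable percentage = round(100·usable/total, 2). The study-level
driving percentage is the unweighted mean of the three driving scenarios'
rounded percentages, rounded again to two decimals; rest is excluded
(it is not driving). Unweighted rather than minute-weighted pooling keeps
the headline consistent with the per-scenario figures (the driving
scenarios have equal totals anyway). The daily projection multiplies the
driving percentage by an average daily driving time (default 30 min) and
is reported unrounded to two decimals.

## Problem sizes

The test suite works on 5–120 s recordings and 20-seed benchmark suites;
the acceptance script regenerates the full 19-subject, 950-minute study
(about half a minute end to end) plus a 20-seed detector benchmark and a
500-candidate STAPLE recovery experiment. These sizes give stable
aggregate statistics while keeping every run comfortably reproducible on
a laptop.

## Known limitations

* The generator's artifact statistics are calibrated, not measured; the
  absolute usable percentages it produces are therefore a property of the
  chosen regime, and only their qualitative structure (rest calmer than
  driving; fusion ≥ median rater; SNR negative and ordering with noise
  level) generalizes.
* STAPLE specificity is relative to candidate windows, not time.
* The EM often walks slowly along a likelihood ridge and hits the 100-
  sweep cap before the 10⁻⁶ parameter tolerance; estimates are stable to
  well below the 0.05 validation tolerance long before that.
* Only the canonical CSV/YAML session format has a reader/writer; an
  externally deposited dataset needs an adapter (`import_external` is the
  extension point).
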