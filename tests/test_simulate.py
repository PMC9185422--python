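"""Generator behavior: determinism, beat spacing, noise statistics, sessions."""

import numpy as np
import pytest

from steerecg.core import Recording
from steerecg.metrics import SnrSpec, snr_db
from steerecg.simulate import (
    ScenarioProfile,
    SubjectParams,
    default_profiles,
    draw_subjects,
    generate_clean_ecg,
    generate_scenario_noise,
    generate_session,
    study_total_minutes,
)


class TestCleanEcg:
    def test_zero_variance_hr_gives_exact_spacing(self):
        subj = SubjectParams("A", base_hr=60.0, hr_sd=0.0)
        _, peaks = generate_clean_ecg(subj, 60.0, 500.0, seed=0)
        assert len(peaks) in (60, 61)
        assert np.all(np.diff(peaks) == 500)

    def test_mean_hr_matches_base_rate(self, subject):
        _, peaks = generate_clean_ecg(subject, 60.0, 500.0, seed=3)
        hr = 60.0 / (np.diff(peaks) / 500.0)
        assert abs(hr.mean() - subject.base_hr) < 2.0

    def test_same_seed_bit_identical(self, subject):
        w1, p1 = generate_clean_ecg(subject, 10.0, 500.0, seed=5)
        w2, p2 = generate_clean_ecg(subject, 10.0, 500.0, seed=5)
        assert np.array_equal(w1, w2)
        assert np.array_equal(p1, p2)

    def test_truth_peaks_are_waveform_maxima(self, subject):
        wave, peaks = generate_clean_ecg(subject, 30.0, 500.0, seed=7)
        for p in peaks:
            lo, hi = p - 25, p + 26
            assert np.argmax(wave[lo:hi]) + lo == p

    def test_rris_positive_and_equal_when_deterministic(self):
        subj = SubjectParams("A", base_hr=72.0, hr_sd=0.0)
        _, peaks = generate_clean_ecg(subj, 60.0, 500.0, seed=0)
        d = np.diff(peaks)
        assert np.all(d > 0)
        assert d.max() - d.min() <= 1  # rounding to the sample grid

    @pytest.mark.parametrize("duration,fs", [(-1.0, 500.0), (0.0, 500.0), (10.0, -5.0)])
    def test_rejects_nonpositive_time_args(self, subject, duration, fs):
        with pytest.raises(ValueError, match="duration|fs"):
            generate_clean_ecg(subject, duration, fs, seed=0)

    def test_ar1_switch_preserves_marginal_spread(self):
        flat = SubjectParams("A", base_hr=70.0, hr_sd=1.5, hr_ar1=0.0)
        corr = SubjectParams("A", base_hr=70.0, hr_sd=1.5, hr_ar1=0.8)
        _, p0 = generate_clean_ecg(flat, 600.0, 500.0, seed=9)
        _, p1 = generate_clean_ecg(corr, 600.0, 500.0, seed=9)
        s0, s1 = np.diff(p0).std(), np.diff(p1).std()
        assert s1 == pytest.approx(s0, rel=0.35)
        # but consecutive-interval jumps shrink under positive correlation
        assert np.abs(np.diff(np.diff(p1) / 500.0)).mean() < np.abs(
            np.diff(np.diff(p0) / 500.0)
        ).mean()


class TestScenarioNoise:
    def test_degenerate_profile_is_silent(self):
        profile = ScenarioProfile("rest", 60.0)
        noise, artifacts, dropouts = generate_scenario_noise(profile, 60.0, 500.0, 0)
        assert np.all(noise == 0.0)
        assert artifacts == [] and dropouts == []

    def test_dropout_count_is_poisson(self):
        profile = ScenarioProfile("city", 900.0, dropout_rate=2.0, dropout_mean_len=1.0)
        counts = []
        for seed in range(20):
            _, _, dropouts = generate_scenario_noise(profile, 900.0, 500.0, seed)
            counts.append(len(dropouts))
        # 2/min for 15 min: Poisson(30); sample mean of 20 draws within 3 SE
        # (merging of overlapping dropouts can only shave off a little).
        assert abs(np.mean(counts) - 30.0) < 3.0 * np.sqrt(30.0 / 20.0) + 1.0

    def test_intervals_stay_inside_recording(self):
        profile = ScenarioProfile(
            "rural", 120.0, dropout_rate=5.0, dropout_mean_len=10.0, artifact_rate=10.0
        )
        n = int(120.0 * 500.0)
        _, artifacts, dropouts = generate_scenario_noise(profile, 120.0, 500.0, 1)
        for iv in artifacts + dropouts:
            assert 0 <= iv.start < iv.end <= n

    def test_broadband_noise_sd(self):
        profile = ScenarioProfile("rest", 300.0, noise_sd_wheel=0.05)
        noise, _, _ = generate_scenario_noise(profile, 300.0, 500.0, 2)
        assert noise.std() == pytest.approx(0.05, rel=0.02)


class TestSession:
    def test_default_study_layout_totals_950_minutes(self):
        assert study_total_minutes(19) == pytest.approx(950.0)

    def test_default_scenario_durations(self):
        profs = default_profiles()
        assert profs["rest"].duration == 300.0
        for name in ("city", "highway", "rural"):
            assert profs[name].duration == 900.0

    def test_noiseless_wheel_is_attenuated_reference(self):
        subj = SubjectParams("A", base_hr=65.0, hr_sd=1.0, wheel_attenuation=0.4)
        profs = {"rest": ScenarioProfile("rest", 30.0)}
        recs, truth = generate_session(subj, profs, 500.0, seed=4)
        ref = next(r for r in recs if r.channel == "reference")
        wheel = next(r for r in recs if r.channel == "wheel")
        assert truth["rest"].dropout_intervals == []
        np.testing.assert_allclose(wheel.samples, 0.4 * ref.samples, atol=1e-12)

    def test_snr_decreases_with_noise_level(self):
        subj = SubjectParams("A", base_hr=70.0, hr_sd=0.0, wheel_attenuation=0.5)
        snrs = []
        for sd in (0.02, 0.06, 0.18):
            profs = {"rest": ScenarioProfile("rest", 120.0, noise_sd_wheel=sd)}
            recs, _ = generate_session(subj, profs, 500.0, seed=6)
            wheel = next(r for r in recs if r.channel == "wheel")
            snrs.append(snr_db(wheel, 70.0 / 60.0, SnrSpec(segment=60.0)).mean_db)
        assert snrs[0] > snrs[1] > snrs[2]

    def test_channels_share_truth_and_length(self, subject):
        profs = {
            "rest": ScenarioProfile("rest", 20.0, noise_sd_wheel=0.05),
            "city": ScenarioProfile("city", 25.0, noise_sd_wheel=0.05),
        }
        recs, truth = generate_session(subject, profs, 500.0, seed=8)
        assert len(recs) == 4
        for sc, dur in (("rest", 20.0), ("city", 25.0)):
            pair = [r for r in recs if r.scenario == sc]
            assert {r.channel for r in pair} == {"reference", "wheel"}
            assert all(len(r.samples) == int(dur * 500) for r in pair)
            assert truth[sc].peaks[-1] < int(dur * 500)

    def test_duplicate_scenarios_rejected(self, subject):
        profs = [ScenarioProfile("rest", 10.0), ScenarioProfile("rest", 20.0)]
        with pytest.raises(ValueError, match="duplicate"):
            generate_session(subject, profs, 500.0, seed=0)

    def test_session_determinism(self, subject):
        profs = {"rest": ScenarioProfile("rest", 15.0, noise_sd_wheel=0.05,
                                         dropout_rate=2.0, artifact_rate=2.0)}
        r1, t1 = generate_session(subject, profs, 500.0, seed=12)
        r2, t2 = generate_session(subject, profs, 500.0, seed=12)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(t1["rest"].peaks, t2["rest"].peaks)
        assert t1["rest"].dropout_intervals == t2["rest"].dropout_intervals

    def test_cohort_draw_respects_invariants(self):
        for s in draw_subjects(19, seed=0):
            assert 40.0 <= s.base_hr <= 180.0
            assert s.hr_sd >= 0.0
            assert 0.0 < s.wheel_attenuation <= 1.0
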