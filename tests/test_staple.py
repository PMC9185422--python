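"""STAPLE fusion: clustering, EM fixed points, parameter recovery, refinement."""

import numpy as np
import pytest

from steerecg.core import BeatAnnotation, Recording
from steerecg.detectors import default_bank, f1_score, run_bank
from steerecg.simulate import SubjectParams, generate_clean_ecg
from steerecg.staple import (
    DecisionMatrix,
    auto_prior,
    build_decision_matrix,
    consensus_refine,
    simulate_decision_matrix,
    staple_em,
)

FS = 500.0


def _ann(peaks, name="d"):
    return BeatAnnotation(np.asarray(peaks, dtype=np.int64), name, FS)


class TestDecisionMatrix:
    def test_identical_peak_lists_are_unanimous(self):
        peaks = [500, 1000, 1500, 2000]
        m = build_decision_matrix([_ann(peaks, "a"), _ann(peaks, "b"), _ann(peaks, "c")])
        np.testing.assert_array_equal(m.candidates, peaks)
        assert np.all(m.votes == 1)

    def test_within_tolerance_offsets_merge(self):
        # 10 ms offset at 500 Hz = 5 samples, well under the 50 ms window
        a = [500, 1000, 1500]
        b = [505, 1005, 1505]
        m = build_decision_matrix([_ann(a, "a"), _ann(b, "b")])
        assert m.n_candidates == 3
        assert np.all(m.votes == 1)

    def test_spurious_peak_gets_single_vote(self):
        # hand-worked clustering: detector c has one extra peak 300 ms away
        a = [500, 1000]
        b = [502, 998]
        c = [500, 1000, 1150]
        m = build_decision_matrix([_ann(a, "a"), _ann(b, "b"), _ann(c, "c")])
        assert m.n_candidates == 3
        assert list(m.votes.sum(axis=1)) == [3, 3, 1]
        assert m.candidates[2] == 1150

    def test_candidates_spaced_by_tolerance(self):
        rng = np.random.default_rng(0)
        peaks = [np.sort(rng.choice(50_000, 80, replace=False)) for _ in range(3)]
        anns = [_ann(np.unique(p), f"d{i}") for i, p in enumerate(peaks)]
        m = build_decision_matrix(anns, FS, tolerance=0.05)
        if m.n_candidates > 1:
            assert np.all(np.diff(m.candidates) >= 1)

    def test_all_empty_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            m = build_decision_matrix([_ann([], "a"), _ann([], "b")])
        assert m.n_candidates == 0

    def test_fewer_than_two_annotations_rejected(self):
        with pytest.raises(ValueError, match="two"):
            build_decision_matrix([_ann([1, 2], "a")])


class TestStapleEm:
    def test_unanimous_votes_fixed_point(self):
        n = 20
        m = DecisionMatrix(
            np.arange(n, dtype=np.int64) * 500,
            np.ones((n, 3), dtype=np.int8),
            ["a", "b", "c"],
            FS,
        )
        res = staple_em(m, prior=0.9)
        assert np.all(res.posteriors >= 0.5)
        assert len(res.consensus) == n
        assert np.all(res.p >= 1.0 - 1e-5)

    def test_parameter_recovery(self):
        """EM recovers known rater sensitivities/specificities to +/-0.05."""
        p_true = np.array([0.95, 0.80, 0.60])
        q_true = np.array([0.99, 0.95, 0.90])
        m, truth = simulate_decision_matrix(p_true, q_true, 0.30, 500, seed=12345)
        res = staple_em(m, prior=0.30)
        np.testing.assert_allclose(res.p, p_true, atol=0.05)
        np.testing.assert_allclose(res.q, q_true, atol=0.05)
        # the consensus recovers the latent truth almost everywhere
        agree = np.mean((res.posteriors >= 0.5) == truth)
        assert agree >= 0.9

    def test_log_likelihood_nondecreasing(self):
        m, _ = simulate_decision_matrix(
            np.array([0.9, 0.7, 0.6]), np.array([0.95, 0.9, 0.85]), 0.4, 300, seed=7
        )
        res = staple_em(m)
        ll = np.asarray(res.log_likelihood)
        assert np.all(np.diff(ll) >= -1e-9)

    def test_two_candidate_toy_matrix_ordering(self):
        # votes [[1,1],[1,0]]: the unanimously voted candidate cannot rank lower
        m = DecisionMatrix(
            np.array([0, 500], dtype=np.int64),
            np.array([[1, 1], [1, 0]], dtype=np.int8),
            ["a", "b"],
            FS,
        )
        res = staple_em(m, prior=0.5)
        assert res.posteriors[0] >= res.posteriors[1]

    def test_detector_permutation_equivariance(self):
        m, _ = simulate_decision_matrix(
            np.array([0.95, 0.8, 0.6]), np.array([0.99, 0.95, 0.9]), 0.3, 400, seed=3
        )
        res = staple_em(m, prior=0.3)
        perm = [2, 0, 1]
        m2 = DecisionMatrix(
            m.candidates, m.votes[:, perm], [m.detector_names[i] for i in perm], FS
        )
        res2 = staple_em(m2, prior=0.3)
        np.testing.assert_allclose(res2.p, res.p[perm], atol=1e-9)
        np.testing.assert_allclose(res2.q, res.q[perm], atol=1e-9)
        np.testing.assert_array_equal(res2.consensus.peaks, res.consensus.peaks)

    def test_threshold_monotonicity(self):
        m, _ = simulate_decision_matrix(
            np.array([0.9, 0.8, 0.7]), np.array([0.95, 0.9, 0.85]), 0.3, 300, seed=5
        )
        res = staple_em(m)
        for thr in (0.5, 0.7, 0.9):
            higher = np.sum(res.posteriors >= thr)
            lower = np.sum(res.posteriors >= 0.5)
            assert higher <= lower

    def test_empty_matrix_rejected(self):
        m = DecisionMatrix(
            np.array([], dtype=np.int64), np.zeros((0, 2), dtype=np.int8), ["a", "b"], FS
        )
        with pytest.raises(ValueError, match="empty"):
            staple_em(m)

    def test_invalid_prior_rejected(self):
        m, _ = simulate_decision_matrix(
            np.array([0.9, 0.8]), np.array([0.9, 0.8]), 0.3, 50, seed=0
        )
        with pytest.raises(ValueError, match="prior"):
            staple_em(m, prior=1.5)

    def test_auto_prior_counts_majority_votes(self):
        votes = np.array([[1, 1, 1], [1, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=np.int8)
        m = DecisionMatrix(
            np.arange(4, dtype=np.int64) * 500, votes, ["a", "b", "c"], FS
        )
        assert auto_prior(m) == pytest.approx(0.5)  # 2 of 4 have >= 1.5 votes


class TestConsensusRefine:
    def test_snap_on_clean_ecg_moves_little(self):
        subj = SubjectParams("A", base_hr=70.0, hr_sd=1.0)
        wave, truth = generate_clean_ecg(subj, 30.0, FS, seed=2)
        rec = Recording(wave, FS, "reference", "rest", "A")
        anns = run_bank(default_bank(), rec)
        m = build_decision_matrix(anns, FS)
        res = staple_em(m)
        refined = consensus_refine(res, rec)
        assert f1_score(refined, truth, 0.01) >= 0.95  # within 5 samples
        before = res.consensus.peaks
        for b, a in zip(before, refined.peaks):
            assert abs(int(a) - int(b)) <= int(0.05 * FS)

    def test_empty_consensus_passthrough(self):
        empty = BeatAnnotation(np.array([], dtype=np.int64), "consensus", FS)
        from steerecg.staple import StapleResult

        res = StapleResult(
            consensus=empty,
            p=np.array([0.5]),
            q=np.array([0.5]),
            posteriors=np.array([]),
            candidates=np.array([], dtype=np.int64),
            detector_names=["a"],
            iterations=0,
            converged=True,
        )
        rec = Recording(np.zeros(5000), FS)
        assert len(consensus_refine(res, rec)) == 0

    def test_colliding_candidates_keep_higher_posterior(self):
        from steerecg.staple import StapleResult

        x = np.zeros(3000)
        x[1000] = 1.0  # single sharp maximum
        rec = Recording(x, FS)
        cand = np.array([995, 1005], dtype=np.int64)
        res = StapleResult(
            consensus=BeatAnnotation(cand, "consensus", FS),
            p=np.array([0.9]),
            q=np.array([0.9]),
            posteriors=np.array([0.8, 0.95]),
            candidates=cand,
            detector_names=["a"],
            iterations=1,
            converged=True,
        )
        refined = consensus_refine(res, rec)
        assert len(refined) == 1
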