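"""STAPLE fusion of R-peak detector outputs.

STAPLE (simultaneous truth and performance level estimation) treats each
detector as a rater of unknown sensitivity p and specificity q and
alternates between (E) computing the posterior probability that each
candidate event is a true beat given the current (p, q) and a prior
prevalence, and (M) re-estimating each rater's (p, q) from the
posteriors.  The consensus is the posterior >= 0.5 set — a weighted
majority vote in which reliable detectors weigh more.

STAPLE is defined over per-item binary decisions, while R-peak detectors
emit point events; :func:`build_decision_matrix` bridges the two by
single-linkage clustering of the pooled detections (peaks closer than a
matching tolerance, default 50 ms — half a typical QRS width — fall into
one candidate window).  Specificity is estimated over candidate windows
only; no background grid of non-events is sampled, which keeps q
interpretable as "stays silent when the other detectors saw something
spurious".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from steerecg.core import BeatAnnotation, Recording
from steerecg.preprocess import FilterSpec, bandpass_array

logger = logging.getLogger(__name__)

_EPS = 1e-6


@dataclass
class DecisionMatrix:
    """Candidate-window x detector vote table.

    ``candidates`` are representative sample indices (median of the
    member peaks of each cluster), strictly increasing and at least
    ``tolerance * fs`` apart; ``votes[c, d] = 1`` iff detector ``d``
    fired inside candidate window ``c``.
    """

    candidates: np.ndarray
    votes: np.ndarray
    detector_names: list[str]
    fs: float
    tolerance: float = 0.05

    def __post_init__(self) -> None:
        self.candidates = np.asarray(self.candidates, dtype=np.int64)
        self.votes = np.asarray(self.votes, dtype=np.int8)
        if self.votes.shape != (len(self.candidates), len(self.detector_names)):
            raise ValueError(
                f"votes shape {self.votes.shape} does not match "
                f"{len(self.candidates)} candidates x {len(self.detector_names)} detectors"
            )

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


@dataclass
class StapleResult:
    """Consensus beats plus estimated rater performance.

    ``p[d]`` is detector d's estimated sensitivity (fires given a true
    beat), ``q[d]`` its specificity over candidate windows (silent given
    a non-beat), ``posteriors[c]`` the probability candidate c is a true
    beat.
    """

    consensus: BeatAnnotation
    p: np.ndarray
    q: np.ndarray
    posteriors: np.ndarray
    candidates: np.ndarray
    detector_names: list[str]
    iterations: int
    converged: bool
    log_likelihood: list[float] = field(default_factory=list)


def build_decision_matrix(
    annotations: list[BeatAnnotation], fs: float | None = None, tolerance: float = 0.05
) -> DecisionMatrix:
    """Cluster pooled detector peaks into candidate windows with votes.

    Single-linkage chaining: pooled peaks are sorted and split wherever
    the gap between neighbours reaches ``tolerance * fs``, so every peak
    of every detector lands in exactly one candidate and merged
    candidates stay at least ``tolerance * fs`` apart.  The candidate
    representative is the median member index.
    """
    if len(annotations) < 2:
        raise ValueError("need at least two annotations to build a decision matrix")
    if fs is None:
        fs = annotations[0].fs
    names = [ann.provenance for ann in annotations]

    pooled = [
        (int(p), d) for d, ann in enumerate(annotations) for p in ann.peaks
    ]
    if not pooled:
        warnings.warn("all annotations are empty; returning an empty decision matrix")
        return DecisionMatrix(
            np.array([], dtype=np.int64),
            np.zeros((0, len(annotations)), dtype=np.int8),
            names,
            fs,
            tolerance,
        )
    pooled.sort()
    gap = tolerance * fs

    clusters: list[list[tuple[int, int]]] = [[pooled[0]]]
    for item in pooled[1:]:
        if item[0] - clusters[-1][-1][0] < gap:
            clusters[-1].append(item)
        else:
            clusters.append([item])

    candidates = np.array(
        [int(np.median([p for p, _ in cl])) for cl in clusters], dtype=np.int64
    )
    votes = np.zeros((len(clusters), len(annotations)), dtype=np.int8)
    for c, cl in enumerate(clusters):
        for _, d in cl:
            votes[c, d] = 1
    return DecisionMatrix(candidates, votes, names, fs, tolerance)


def auto_prior(matrix: DecisionMatrix) -> float:
    """Prevalence prior: fraction of candidates with at least half the votes.

    Clamped to [0.05, 0.95] so the EM never starts from a degenerate
    prior.
    """
    if matrix.n_candidates == 0:
        return 0.5
    half = matrix.votes.shape[1] / 2.0
    frac = float(np.mean(matrix.votes.sum(axis=1) >= half))
    return float(np.clip(frac, 0.05, 0.95))


def staple_em(
    matrix: DecisionMatrix,
    prior: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> StapleResult:
    """Run the STAPLE EM on a decision matrix.

    ``prior`` is the prevalence of true beats among candidates (default:
    :func:`auto_prior`).  Iteration stops when the largest change in any
    (p, q) falls below ``tol`` or after ``max_iter`` sweeps.  The
    procedure is deterministic.  Rater parameters are clamped to
    ``[1e-6, 1 - 1e-6]`` so unanimous columns cannot produce 0/0.
    """
    if matrix.n_candidates == 0:
        raise ValueError("decision matrix is empty")
    if prior is None:
        prior = auto_prior(matrix)
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must be in (0, 1), got {prior}")

    v = matrix.votes.astype(float)  # (n_candidates, n_detectors)
    n_det = v.shape[1]
    p = np.full(n_det, 0.9)
    q = np.full(n_det, 0.9)

    loglik: list[float] = []
    converged = False
    iterations = 0
    w = np.full(matrix.n_candidates, prior)
    for iterations in range(1, max_iter + 1):
        # E-step: posterior that each candidate is a true beat.
        log_a = np.log(prior) + v @ np.log(p) + (1 - v) @ np.log(1 - p)
        log_b = np.log(1 - prior) + v @ np.log(1 - q) + (1 - v) @ np.log(q)
        m = np.maximum(log_a, log_b)
        denom = np.exp(log_a - m) + np.exp(log_b - m)
        w = np.exp(log_a - m) / denom
        loglik.append(float(np.sum(m + np.log(denom))))

        # M-step: per-detector sensitivity/specificity from posteriors.
        sw = w.sum()
        snw = (1.0 - w).sum()
        p_new = (w @ v) / sw if sw > 0 else p
        q_new = ((1.0 - w) @ (1.0 - v)) / snw if snw > 0 else q
        p_new = np.clip(p_new, _EPS, 1.0 - _EPS)
        q_new = np.clip(q_new, _EPS, 1.0 - _EPS)

        delta = max(np.max(np.abs(p_new - p)), np.max(np.abs(q_new - q)))
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    consensus_mask = w >= 0.5
    consensus = BeatAnnotation(
        matrix.candidates[consensus_mask], provenance="consensus", fs=matrix.fs
    )
    return StapleResult(
        consensus=consensus,
        p=p,
        q=q,
        posteriors=w,
        candidates=matrix.candidates,
        detector_names=list(matrix.detector_names),
        iterations=iterations,
        converged=converged,
        log_likelihood=loglik,
    )


def simulate_decision_matrix(
    sensitivities: np.ndarray,
    specificities: np.ndarray,
    prevalence: float,
    n_candidates: int,
    seed: int | np.random.SeedSequence = 0,
    fs: float = 500.0,
) -> tuple[DecisionMatrix, np.ndarray]:
    """Draw a decision matrix from known rater performance.

    Each candidate is a true beat with probability ``prevalence``;
    rater d then votes 1 with probability ``sensitivities[d]`` on true
    beats and ``1 - specificities[d]`` on non-beats.  Used to validate
    that the EM recovers the generating parameters.

    Returns the matrix and the latent truth vector.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(sensitivities, dtype=float)
    q = np.asarray(specificities, dtype=float)
    truth = rng.random(n_candidates) < prevalence
    fire_prob = np.where(truth[:, None], p[None, :], 1.0 - q[None, :])
    votes = (rng.random((n_candidates, len(p))) < fire_prob).astype(np.int8)
    candidates = np.arange(n_candidates, dtype=np.int64) * int(fs)  # 1 s apart
    names = [f"rater{d}" for d in range(len(p))]
    return DecisionMatrix(candidates, votes, names, fs), truth


def consensus_refine(
    result: StapleResult, rec: Recording, halfwidth_s: float = 0.05
) -> BeatAnnotation:
    """Snap consensus beats to local maxima of the band-passed signal.

    Each consensus index moves to the maximum of the 0.5–25 Hz filtered
    recording within +/-50 ms.  If two candidates snap to the same
    maximum, the one with the higher posterior survives.
    """
    if len(result.consensus) == 0:
        return BeatAnnotation(np.array([], dtype=np.int64), "consensus", rec.fs)
    filtered = bandpass_array(rec.samples, rec.fs, FilterSpec())
    hw = int(round(halfwidth_s * rec.fs))
    mask = result.posteriors >= 0.5
    cand = result.candidates[mask]
    post = result.posteriors[mask]

    snapped: dict[int, float] = {}
    for c, w in zip(cand, post):
        lo = max(int(c) - hw, 0)
        hi = min(int(c) + hw + 1, len(filtered))
        s = lo + int(np.argmax(filtered[lo:hi]))
        if s not in snapped or w > snapped[s]:
            snapped[s] = float(w)
    peaks = np.array(sorted(snapped), dtype=np.int64)
    return BeatAnnotation(peaks, provenance="consensus", fs=rec.fs)
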