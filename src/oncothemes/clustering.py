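"""Consensus clustering of tumors with a PAM (k-medoids) base learner.

Tumors are clustered either in SGA space (binary event vectors, Jaccard
distance) or in topic space (document-topic allocations, Euclidean
distance). Robustness comes from consensus clustering: PAM is run on many
random subsamples of the cohort and the fraction of runs in which two
tumors co-cluster (among runs co-sampling them) forms a consensus matrix;
the final partition is PAM on 1 - consensus.

PAM itself is the classic BUILD + steepest-descent SWAP algorithm
minimizing total dissimilarity of points to their nearest medoid; the SWAP
deltas are evaluated with the FastPAM-style vectorization, which changes
nothing about the optimum found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

DEFAULT_SUBSAMPLE = 0.8


@dataclass
class FeatureSpace:
    """Tumor feature matrix plus the distance appropriate to it."""

    kind: str                      # "sga" or "topic"
    vectors: np.ndarray            # (n_tumors, n_features)
    tumor_ids: list[str]
    # defaults: Jaccard for binary SGA vectors; total-variation (L1 /
    # "cityblock") for topic allocations, the natural metric between
    # probability vectors. Any scipy pdist metric may be passed instead.
    distance: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("sga", "topic"):
            raise ValueError(f"unknown feature space kind {self.kind!r}")
        if self.distance is None:
            self.distance = "jaccard" if self.kind == "sga" else "cityblock"
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.tumor_ids):
            raise ValueError("vectors/tumor_ids length mismatch")

    def distance_matrix(self) -> np.ndarray:
        if self.vectors.shape[0] != len(set(self.tumor_ids)):
            raise ValueError("duplicate tumor ids")
        vec = self.vectors
        if self.distance == "jaccard":
            vec = vec.astype(bool)
        return squareform(pdist(vec, metric=self.distance))


@dataclass
class ConsensusResult:
    k: int
    consensus: np.ndarray
    assignments: dict[str, int]
    robustness: float
    tumor_ids: list[str] = field(default_factory=list)

    def labels(self) -> np.ndarray:
        return np.asarray([self.assignments[t] for t in self.tumor_ids])


def _swap_phase(D: np.ndarray, medoids: np.ndarray, max_iter: int) -> np.ndarray:
    """Steepest-descent SWAP from the given medoid set to a local optimum."""
    n = D.shape[0]
    k = len(medoids)
    for _ in range(max_iter):
        Dm = D[medoids]                       # (k, n)
        order = np.argsort(Dm, axis=0, kind="stable")
        n1 = order[0]                         # index into medoids
        d1 = Dm[n1, np.arange(n)]
        d2 = Dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        others = np.setdiff1d(np.arange(n), medoids)
        if len(others) == 0:
            break
        Dh = D[np.ix_(others, np.arange(n))]  # (n-k, n)
        # shared term: point moves to h if closer than its current medoid
        shared = np.minimum(Dh - d1[None, :], 0.0)
        delta = np.tile(shared.sum(axis=1)[:, None], (1, k))
        # correction for points whose nearest medoid is the one removed
        for mi in range(k):
            sel = n1 == mi
            if not sel.any():
                continue
            corr = np.minimum(Dh[:, sel], d2[None, sel]) - d1[None, sel]
            delta[:, mi] += (corr - shared[:, sel]).sum(axis=1)
        hi, mi = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[hi, mi] > -1e-12:
            break
        medoids = np.asarray(sorted(np.r_[np.delete(medoids, mi), others[hi]]))
    return medoids


def _medoid_objective(D: np.ndarray, medoids: np.ndarray) -> float:
    return float(D[medoids].min(axis=0).sum())


def pam(
    distmat: np.ndarray,
    k: int,
    seed: int | None = None,
    max_iter: int = 200,
    restarts: int = 3,
) -> np.ndarray:
    """k-medoids via BUILD + steepest SWAP; returns labels 0..k-1.

    SWAP converges to a local optimum of the total within-cluster distance
    to medoids; to soften its (real, if rare) local optima the search is
    repeated from ``restarts`` additional random medoid seeds and the best
    solution kept. Deterministic given ``seed`` and input order (ties break
    toward the smallest index); with ``restarts=0`` this is the classic
    deterministic BUILD + SWAP and draws no random numbers.
    """
    D = np.asarray(distmat, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix must have a zero diagonal")
    if k > n or k < 1:
        raise ValueError(f"k={k} out of range for n={n}")

    # tiny instances: the medoid-set space is enumerable, solve exactly
    if comb(n, k) <= 300:
        best, best_obj = None, np.inf
        for cand in combinations(range(n), k):
            obj = _medoid_objective(D, np.asarray(cand))
            if obj < best_obj - 1e-12:
                best, best_obj = np.asarray(cand), obj
        labels = np.argmin(D[best], axis=0)
        labels[best] = np.arange(len(best))
        return labels

    # BUILD: greedy seeding
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dnear = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dnear[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        dnear = np.minimum(dnear, D[c])

    best = _swap_phase(D, np.asarray(sorted(medoids)), max_iter)
    best_obj = _medoid_objective(D, best)
    if restarts > 0 and k < n:
        rng = np.random.default_rng(0 if seed is None else seed)
        for _ in range(restarts):
            start = np.sort(rng.choice(n, size=k, replace=False))
            cand = _swap_phase(D, start, max_iter)
            obj = _medoid_objective(D, cand)
            if obj < best_obj - 1e-12:
                best, best_obj = cand, obj
    labels = np.argmin(D[best], axis=0)
    labels[best] = np.arange(len(best))  # medoids belong to themselves
    return labels


def pam_objective(distmat: np.ndarray, labels: np.ndarray) -> float:
    """Total distance to the implied medoid of each cluster (for checks)."""
    D = np.asarray(distmat, dtype=float)
    total = 0.0
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        sub = D[np.ix_(idx, idx)]
        total += float(sub.sum(axis=1).min())
    return total


def consensus_cluster(
    space: FeatureSpace,
    k_range,
    reps: int,
    subsample: float = DEFAULT_SUBSAMPLE,
    seed: int = 0,
) -> list[ConsensusResult]:
    """Consensus clustering over a range of k.

    For each k, ``reps`` PAM runs on random ``subsample`` fractions of the
    tumors (without replacement) are summarized into a consensus matrix;
    final assignments are PAM at the same k on 1 - consensus. Robustness is
    the mean consensus over within-cluster pairs of the final partition.
    """
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    D = space.distance_matrix()
    n = D.shape[0]
    m = max(2, int(round(subsample * n)))
    rng = np.random.default_rng(seed)
    results = []
    for k in sorted(int(k) for k in k_range):
        co = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(reps):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            labels = pam(D[np.ix_(idx, idx)], k)
            sampled[np.ix_(idx, idx)] += 1.0
            same = labels[:, None] == labels[None, :]
            co[np.ix_(idx, idx)] += same
        off = ~np.eye(n, dtype=bool)
        if (sampled[off].reshape(n, n - 1) == 0).all(axis=1).any():
            raise ValueError(
                "some tumor was never co-sampled with any other; increase reps"
            )
        with np.errstate(invalid="ignore"):
            consensus = np.where(sampled > 0, co / np.maximum(sampled, 1), 0.0)
        np.fill_diagonal(consensus, np.where(np.diag(sampled) > 0, 1.0, 0.0))
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        dist = 0.5 * (dist + dist.T)  # exact symmetry against float noise
        labels = pam(dist, k)
        within = (labels[:, None] == labels[None, :]) & off
        robustness = float(consensus[within].mean()) if within.any() else 1.0
        results.append(
            ConsensusResult(
                k=k,
                consensus=consensus,
                assignments=dict(zip(space.tumor_ids, labels.tolist())),
                robustness=robustness,
                tumor_ids=list(space.tumor_ids),
            )
        )
    return results


def compare_spaces(
    sga_result: ConsensusResult,
    topic_result: ConsensusResult,
    truth: dict[str, int],
) -> dict[str, float]:
    """ARI of each space's partition against ground truth, plus robustness.

    With a single-cluster truth, scikit-learn's adjusted Rand index is used
    as-is (it returns 1.0 when the compared partition is also trivial and
    0.0 otherwise).
    """
    if set(sga_result.assignments) != set(topic_result.assignments):
        raise ValueError("results cover different tumors")
    tumors = sga_result.tumor_ids
    y = [truth[t] for t in tumors]
    ari_sga = adjusted_rand_score(y, [sga_result.assignments[t] for t in tumors])
    ari_topic = adjusted_rand_score(y, [topic_result.assignments[t] for t in tumors])
    return {
        "ari_sga": float(ari_sga),
        "ari_topic": float(ari_topic),
        "robustness_sga": sga_result.robustness,
        "robustness_topic": topic_result.robustness,
    }
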