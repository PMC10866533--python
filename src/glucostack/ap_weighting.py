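"""Adaptive base-model weighting via affinity-propagation clustering.

Validation samples are represented as points in base-model prediction space
(one coordinate per base model, taken at the final horizon step).  A weighted
similarity matrix

    S_ij = −dis_ij − α·(var_i + var_j)

augments the negated Euclidean distance ``dis_ij`` with each point's own
feature variance ``var_i`` (mean squared deviation of the point's
coordinates from their mean), scaled by the weight coefficient α.  Affinity
propagation clusters the points; each base model k is then scored by the
cluster-variance sum

    w_k = Σ_clusters (1/C) · Σ_{j in cluster} (x_jk − μ_cluster,k)²

(C = number of clusters, μ the per-cluster per-model mean), normalized to a
convex weight vector.  As printed, the normalization upweights high-variance
models; an ``invert`` mode (w → 1/(w+ε) before normalizing) is provided for
the opposite — arguably more intuitive — convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .base_models import PredictionMatrix

logger = logging.getLogger(__name__)

EPSILON = 1e-8


@dataclass(frozen=True)
class SimilarityConfig:
    """Similarity and AP hyperparameters (α default 0.5; canonical AP defaults)."""

    similarity_alpha: float = 0.5
    preference: float | None = None    # None → median of off-diagonal similarities
    damping: float = 0.5
    extra_dampings: tuple = (0.7, 0.9)  # fallback ladder; best net similarity wins
    max_iter: int = 200
    convergence_iter: int = 15
    sample_cap: int = 500
    seed: int = 0

    def validate(self) -> None:
        if not 0.5 <= self.damping < 1:
            raise ValueError("damping must lie in [0.5, 1)")
        if self.similarity_alpha < 0:
            raise ValueError("similarity_alpha must be nonnegative")


@dataclass(frozen=True)
class WeightedSimilarityMatrix:
    S: np.ndarray
    points: np.ndarray


@dataclass(frozen=True)
class ClusterAssignment:
    exemplar_indices: np.ndarray   # sorted exemplar row indices
    labels: np.ndarray             # per-point exemplar index into ``exemplar_indices``
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.exemplar_indices)

    def cluster_means(self, X: np.ndarray) -> np.ndarray:
        """Per-cluster per-feature means, shape (n_clusters, n_features)."""
        X = np.asarray(X, dtype=float)
        return np.vstack([X[self.labels == c].mean(axis=0)
                          for c in range(self.n_clusters)])


@dataclass(frozen=True)
class WeightVector:
    raw: np.ndarray
    weights: np.ndarray
    invert_flag: bool = False


def weighted_similarity(points: np.ndarray,
                        config: SimilarityConfig = SimilarityConfig()) -> WeightedSimilarityMatrix:
    """Build the α-weighted similarity matrix over row-vector points."""
    config.validate()
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("points must be an n×d matrix with n >= 2, d >= 1")
    if not np.isfinite(X).all():
        raise ValueError("points contain non-finite entries")
    diff = X[:, None, :] - X[None, :, :]
    dis = np.sqrt((diff ** 2).sum(axis=2))
    var = ((X - X.mean(axis=1, keepdims=True)) ** 2).mean(axis=1)
    S = -dis - config.similarity_alpha * (var[:, None] + var[None, :])
    return WeightedSimilarityMatrix(S=S, points=X)


def _median_off_diagonal(S: np.ndarray) -> float:
    n = S.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(np.median(S[mask]))


def affinity_propagation(S_or_matrix,
                         config: SimilarityConfig = SimilarityConfig()) -> ClusterAssignment:
    """Cluster by affinity propagation on a precomputed similarity matrix.

    The preference (self-similarity) defaults to the median of off-diagonal
    similarities.  Message passing is a fixed-point iteration that can settle
    in a suboptimal labeling at any single damping factor, so the algorithm
    is run at a short ladder of damping values and the exemplar set with the
    highest net similarity (AP's own objective) is kept.  If no damping
    converges, the points collapse into a single medoid cluster and the
    assignment is flagged unconverged.
    """
    config.validate()
    S = S_or_matrix.S if isinstance(S_or_matrix, WeightedSimilarityMatrix) else np.asarray(
        S_or_matrix, dtype=float)
    n = S.shape[0]
    if n == 1:
        return ClusterAssignment(exemplar_indices=np.array([0]), labels=np.array([0]))
    pref = config.preference if config.preference is not None else _median_off_diagonal(S)
    S = S.copy()
    np.fill_diagonal(S, pref)

    best = None
    best_score = -np.inf
    for damping in (config.damping, *config.extra_dampings):
        ap = AffinityPropagation(
            affinity="precomputed", damping=damping, max_iter=config.max_iter,
            convergence_iter=config.convergence_iter, preference=pref,
            random_state=config.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            labels = ap.fit_predict(S)
        if np.any(labels == -1) or len(ap.cluster_centers_indices_) == 0:
            continue
        score = net_similarity(S, ap.cluster_centers_indices_, pref)
        if score > best_score:
            best, best_score = ap, score
    if best is None:
        logger.warning("affinity propagation did not converge; using one medoid cluster")
        medoid = int(np.argmax(S.sum(axis=1)))
        return ClusterAssignment(exemplar_indices=np.array([medoid]),
                                 labels=np.zeros(n, dtype=int), converged=False)
    ap = best
    exemplars = sorted(int(i) for i in ap.cluster_centers_indices_)
    if n <= 64:  # cheap at small n; quadratic candidate sweeps beyond that
        exemplars = _polish_exemplars(S, exemplars, pref)
    exemplars = np.asarray(exemplars)
    labels = np.argmax(S[:, exemplars], axis=1)
    labels[exemplars] = np.arange(len(exemplars))  # each exemplar labels itself
    return ClusterAssignment(exemplar_indices=exemplars, labels=labels,
                             converged=bool(ap.n_iter_ < config.max_iter))


def _polish_exemplars(S: np.ndarray, exemplars: list[int], pref: float) -> list[int]:
    """Greedy local search on the net-similarity objective.

    Message passing can settle one single-exemplar move away from a better
    labeling; try adding, removing and swapping one exemplar at a time until
    no move improves the objective.  Ties break toward the lowest index.
    """
    n = S.shape[0]
    current = sorted(exemplars)
    score = net_similarity(S, current, pref)
    improved = True
    while improved:
        improved = False
        candidates = []
        ex_set = set(current)
        for j in range(n):                    # add
            if j not in ex_set:
                candidates.append(sorted(current + [j]))
        if len(current) > 1:                  # remove
            for e in current:
                candidates.append([x for x in current if x != e])
        for e in current:                     # swap
            for j in range(n):
                if j not in ex_set:
                    candidates.append(sorted([x for x in current if x != e] + [j]))
        for cand in candidates:
            s = net_similarity(S, cand, pref)
            if s > score + 1e-12:
                current, score, improved = cand, s, True
                break
    return current


def net_similarity(S: np.ndarray, exemplars, preference: float) -> float:
    """Objective AP maximizes: Σ preference(exemplars) + Σ max similarity to an exemplar.

    Shared with the exhaustive-search oracle in the tests.
    """
    S = np.asarray(S, dtype=float)
    exemplars = np.asarray(sorted(exemplars))
    total = preference * len(exemplars)
    for i in range(S.shape[0]):
        if i in exemplars:
            continue
        total += S[i, exemplars].max()
    return float(total)


def cluster_weighted_variance(X: np.ndarray, assignment: ClusterAssignment) -> np.ndarray:
    """Per-model cluster-variance sums w_k (see module docstring)."""
    X = np.asarray(X, dtype=float)
    labels = assignment.labels
    if labels.max() >= assignment.n_clusters or len(labels) != len(X):
        raise ValueError("assignment labels inconsistent with X")
    C = assignment.n_clusters
    w = np.zeros(X.shape[1])
    for c in range(C):
        members = X[labels == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} has no members")
        mu = members.mean(axis=0)
        w += ((members - mu) ** 2).sum(axis=0) / C
    return w


def normalize_weights(raw, invert_flag: bool = False) -> WeightVector:
    """Normalize raw scores to a convex weight vector (sum 1).

    With ``invert_flag`` each score is first mapped to 1/(w+ε), so smaller
    cluster variance yields larger weight.  An all-zero score vector yields
    uniform weights with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw weights must be nonnegative")
    scores = 1.0 / (raw + EPSILON) if invert_flag else raw.copy()
    total = scores.sum()
    if total == 0:
        logger.warning("all raw weights are zero; falling back to uniform weights")
        weights = np.full(len(raw), 1.0 / len(raw))
    else:
        weights = scores / total
    return WeightVector(raw=raw, weights=weights, invert_flag=invert_flag)


def combine_predictions(preds: list, weights) -> PredictionMatrix:
    """Convex combination Σ_k weight_k · pred_k of same-shape prediction matrices."""
    if isinstance(weights, WeightVector):
        weights = weights.weights
    weights = np.asarray(weights, dtype=float)
    mats = [p.values if isinstance(p, PredictionMatrix) else np.asarray(p, dtype=float)
            for p in preds]
    scales = {p.scale for p in preds if isinstance(p, PredictionMatrix)}
    if len(mats) != len(weights):
        raise ValueError("number of prediction matrices must equal number of weights")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("prediction matrices differ in shape")
    combined = sum(w * m for w, m in zip(weights, mats))
    return PredictionMatrix(values=np.asarray(combined), model="weighted",
                            scale=scales.pop() if len(scales) == 1 else "normalized")


class APWeighter(BaseEstimator):
    """Estimator wrapper: fit on (samples × models) prediction points.

    Fitted attributes: ``assignment_``, ``weight_vector_``, ``weights_``.
    """

    def __init__(self, similarity_alpha=0.5, preference=None, damping=0.5,
                 max_iter=200, convergence_iter=15, sample_cap=500,
                 invert_flag=False, seed=0):
        self.similarity_alpha = similarity_alpha
        self.preference = preference
        self.damping = damping
        self.max_iter = max_iter
        self.convergence_iter = convergence_iter
        self.sample_cap = sample_cap
        self.invert_flag = invert_flag
        self.seed = seed

    def _config(self) -> SimilarityConfig:
        return SimilarityConfig(
            similarity_alpha=self.similarity_alpha, preference=self.preference,
            damping=self.damping, max_iter=self.max_iter,
            convergence_iter=self.convergence_iter, sample_cap=self.sample_cap,
            seed=self.seed,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        cfg = self._config()
        cfg.validate()
        if len(X) > cfg.sample_cap:
            rng = np.random.default_rng(cfg.seed)
            idx = np.sort(rng.choice(len(X), size=cfg.sample_cap, replace=False))
            X = X[idx]
        self.points_ = X
        sim = weighted_similarity(X, cfg)
        self.similarity_ = sim
        self.assignment_ = affinity_propagation(sim, cfg)
        raw = cluster_weighted_variance(X, self.assignment_)
        self.weight_vector_ = normalize_weights(raw, invert_flag=self.invert_flag)
        self.weights_ = self.weight_vector_.weights
        return self
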