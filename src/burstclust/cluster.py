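"""Exemplar clustering of bursts by affinity propagation.

Affinity propagation chooses cluster *exemplars* — actual data points that
represent their cluster — by iteratively exchanging two kinds of messages
on the similarity matrix: responsibilities r(i,k), the accumulated evidence
that point k should serve as the exemplar for point i, and availabilities
a(i,k), the accumulated evidence that it is appropriate for i to choose k.
The similarity here is the negated burst-shift spike-time distance; the
diagonal "preference" entries (median off-diagonal similarity times a
multiplier) control how readily points become exemplars and therefore the
emergent number of clusters.

The message passing runs for a fixed number of iterations (200 by
default, no early exit) with damped updates, which together with the
seeded similarity noise makes every run exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples

from .metric import DistanceMatrix

__all__ = [
    "SimilarityMatrix",
    "Clustering",
    "Dendrogram",
    "ConvergenceError",
    "BurstAffinityPropagation",
    "similarity_from_distances",
    "affinity_propagation",
    "build_dendrogram",
    "silhouette_values",
]


class ConvergenceError(RuntimeError):
    """Raised when message passing identifies no exemplar."""


@dataclass
class SimilarityMatrix:
    """Negated distances with seeded noise and scaled diagonal preferences."""

    values: np.ndarray
    p_mult: float
    noise_scale: float
    seed: int | None

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Clustering:
    """Result of affinity propagation over one burst set."""

    exemplars: np.ndarray       # indices of exemplar bursts
    assignment: np.ndarray      # burst index -> exemplar index
    labels: np.ndarray          # burst index -> cluster number (0..K-1)
    n_iter: int
    damping: float

    @property
    def n_clusters(self) -> int:
        return self.exemplars.size

    def members(self, k: int) -> np.ndarray:
        """Indices of the bursts assigned to cluster number ``k``."""
        return np.flatnonzero(self.labels == k)


def similarity_from_distances(
    D: DistanceMatrix | np.ndarray,
    p_mult: float = 1.0,
    noise_scale: float | None = None,
    seed: int | None = 0,
) -> SimilarityMatrix:
    """Similarity matrix for affinity propagation from burst distances.

    Off-diagonal: s(i,k) = -d(i,k) plus independent zero-mean Gaussian
    noise (scale ``noise_scale``; default 1e-6 times the off-diagonal
    similarity range — "very small", and scale-free).  Diagonal: the median
    off-diagonal similarity times ``p_mult``; multipliers > 1 make the
    (negative) preferences more negative and so yield fewer clusters.
    """
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two bursts to build similarities")
    if p_mult <= 0:
        raise ValueError("p_mult must be positive")
    s = -d.astype(float)
    off = ~np.eye(n, dtype=bool)
    off_vals = s[off]
    if noise_scale is None:
        spread = float(off_vals.max() - off_vals.min())
        noise_scale = 1e-6 * spread
        if spread == 0.0:
            warnings.warn(
                "degenerate distance matrix: all off-diagonal distances equal",
                RuntimeWarning, stacklevel=2,
            )
    preference = float(np.median(off_vals)) * p_mult
    out = s.copy()
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_scale, size=(n, n))
        out[off] += noise[off]
    np.fill_diagonal(out, preference)
    return SimilarityMatrix(values=out, p_mult=p_mult,
                            noise_scale=float(noise_scale), seed=seed)


def _message_passing(S: np.ndarray, damping: float, iters: int):
    n = S.shape[0]
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    for _ in range(iters):
        # responsibilities: r(i,k) = s(i,k) - max_{k' != k} [a(i,k') + s(i,k')]
        AS = A + S
        best_k = np.argmax(AS, axis=1)
        best = AS[idx, best_k]
        AS[idx, best_k] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - best[:, None]
        Rnew[idx, best_k] = S[idx, best_k] - second
        R = damping * R + (1.0 - damping) * Rnew
        # availabilities: a(i,k) = min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))
        #                 a(k,k) = sum_{i' != k} max(0, r(i',k))
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        colsum = Rp.sum(axis=0)
        Anew = colsum[None, :] - Rp
        diag = Anew.diagonal().copy()
        Anew = np.minimum(Anew, 0.0)
        np.fill_diagonal(Anew, diag)
        A = damping * A + (1.0 - damping) * Anew
    return R, A


class BurstAffinityPropagation(BaseEstimator, ClusterMixin):
    """Affinity propagation on a precomputed burst distance matrix.

    scikit-learn style estimator: ``fit(X)`` takes a square distance
    matrix (or a :class:`~burstclust.metric.DistanceMatrix`), builds the
    similarity matrix internally, and runs a fixed number of damped
    message-passing iterations.

    Parameters
    ----------
    damping : float in [0, 1)
        Smoothing factor of the message updates (new = damping * old +
        (1 - damping) * new).
    max_iter : int
        Fixed number of message-passing iterations; there is no early
        convergence exit.
    p_mult : float
        Preference multiplier; larger values produce fewer clusters.
    noise_scale : float or None
        Scale of the similarity noise; None selects 1e-6 x the
        off-diagonal range.
    random_state : int or None
        Seed of the similarity noise.

    Attributes
    ----------
    cluster_centers_indices_ : ndarray
        Indices of the exemplar bursts.
    labels_ : ndarray
        Cluster number of every burst.
    assignment_ : ndarray
        Exemplar index of every burst (exemplars map to themselves).
    n_iter_ : int
        Number of iterations run (always ``max_iter``).
    """

    def __init__(self, damping: float = 0.5, max_iter: int = 200,
                 p_mult: float = 1.0, noise_scale: float | None = None,
                 random_state: int | None = 0):
        self.damping = damping
        self.max_iter = max_iter
        self.p_mult = p_mult
        self.noise_scale = noise_scale
        self.random_state = random_state

    def fit(self, X, y=None):
        if not 0.0 <= self.damping < 1.0:
            raise ValueError("damping must be in [0, 1)")
        if isinstance(X, SimilarityMatrix):
            S = X
        else:
            S = similarity_from_distances(
                X, p_mult=self.p_mult, noise_scale=self.noise_scale,
                seed=self.random_state,
            )
        sim = np.asarray(S.values, dtype=float)
        if not np.all(np.isfinite(sim)):
            raise ValueError("similarity matrix must be finite")
        if sim.shape[0] == 1:
            # a single point is trivially its own exemplar
            self.similarity_ = S
            self.cluster_centers_indices_ = np.array([0])
            self.assignment_ = np.array([0])
            self.labels_ = np.array([0])
            self.n_iter_ = 0
            return self
        R, A = _message_passing(sim, self.damping, self.max_iter)
        crit = A + R
        choice = np.argmax(crit, axis=1)  # ties break toward lowest index
        exemplars = np.flatnonzero(choice == np.arange(sim.shape[0]))
        if exemplars.size == 0:
            raise ConvergenceError(
                "affinity propagation identified no exemplar after "
                f"{self.max_iter} iterations (damping={self.damping}, "
                f"p_mult={self.p_mult}); the preferences may be too negative"
            )
        # every non-exemplar joins its most similar exemplar
        assignment = exemplars[np.argmax(sim[:, exemplars], axis=1)]
        assignment[exemplars] = exemplars
        label_of = {e: k for k, e in enumerate(exemplars)}
        self.similarity_ = S
        self.cluster_centers_indices_ = exemplars
        self.assignment_ = assignment
        self.labels_ = np.array([label_of[e] for e in assignment])
        self.n_iter_ = self.max_iter
        return self

    def to_clustering(self) -> Clustering:
        return Clustering(
            exemplars=self.cluster_centers_indices_.copy(),
            assignment=self.assignment_.copy(),
            labels=self.labels_.copy(),
            n_iter=self.n_iter_,
            damping=self.damping,
        )


def affinity_propagation(
    S: SimilarityMatrix, damping: float = 0.5, iters: int = 200
) -> Clustering:
    """Run message passing on a prebuilt similarity matrix."""
    est = BurstAffinityPropagation(damping=damping, max_iter=iters)
    est.fit(S)
    return est.to_clustering()


@dataclass
class Dendrogram:
    """Group-average (UPGMA) merge tree over cluster exemplars."""

    leaf_ids: list
    linkage: np.ndarray  # scipy linkage matrix; empty for a single leaf

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2] if self.linkage.size else np.empty(0)

    def to_newick(self) -> str:
        """Newick string with branch heights as merge distances."""
        n = len(self.leaf_ids)
        if n == 1:
            return f"{self.leaf_ids[0]};"
        names = {i: str(self.leaf_ids[i]) for i in range(n)}
        height = {i: 0.0 for i in range(n)}
        for row_i, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = (h - height[a]) / 2.0
            lb = (h - height[b]) / 2.0
            names[n + row_i] = f"({names[a]}:{la:.6g},{names[b]}:{lb:.6g})"
            height[n + row_i] = h
        return names[n + len(self.linkage) - 1] + ";"


def build_dendrogram(exemplar_ids, D) -> Dendrogram:
    """UPGMA tree over exemplars from their pairwise distances."""
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    ids = list(exemplar_ids)
    if len(ids) == 0:
        raise ValueError("need at least one exemplar")
    if d.shape != (len(ids), len(ids)):
        raise ValueError("distance matrix shape must match exemplar count")
    if len(ids) == 1:
        return Dendrogram(leaf_ids=ids, linkage=np.empty((0, 4)))
    Z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(leaf_ids=ids, linkage=Z)


def silhouette_values(D, assignment) -> np.ndarray:
    """Per-burst silhouette scores from a precomputed distance matrix.

    (b - a) / max(a, b) with a the mean within-cluster distance and b the
    smallest mean distance to another cluster; singleton clusters score 0.
    Requires at least two clusters.
    """
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    labels = np.asarray(assignment)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette values require at least two clusters")
    return silhouette_samples(d, labels, metric="precomputed")
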