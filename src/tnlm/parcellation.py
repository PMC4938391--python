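"""Correlation-affinity graph construction and normalized-cuts parcellation.

The spatio-temporal field is represented as a fully connected graph
G = (V, A) over surface vertices with edge strength

    A(u, v) = exp(d(u)' d(v) / T) = exp(corr(u, v))

for standardized series.  No spatial edges are added: proximity enters only
through the filtering step, which is what makes the comparison between
linear and non-local smoothing informative.  The graph is partitioned into
K networks by multiclass normalized cuts, which maximizes the average
normalized association

    Nassoc(V1..VK) = (1/K) sum_i [ sum_{u,v in Vi} A(u,v)
                                   / sum_{u in Vi, v in V} A(u,v) ].

Self-loops are kept (A(u,u) = e); the inner sums range over all ordered
pairs within each class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from tnlm.filtering import TimeSeriesField

__all__ = [
    "AffinityGraph",
    "Parcellation",
    "affinity_matrix",
    "nassoc_score",
    "ncuts_partition",
]

# dense n x n storage: above this vertex count the affinity alone is > ~2 GB
_DENSE_GUARD = 15_000


@dataclass
class AffinityGraph:
    """Dense symmetric matrix of positive edge strengths over vertex pairs."""

    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError(f"affinity must be square, got {self.A.shape}")

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass
class Parcellation:
    """Integer label in [0, K) per vertex; labels partition the vertex set."""

    labels: np.ndarray
    K: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D integer array")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.K
        ):
            raise ValueError(f"labels outside [0, {self.K})")

    @property
    def n_vertices(self) -> int:
        return self.labels.shape[0]


def affinity_matrix(fld: TimeSeriesField) -> AffinityGraph:
    """A(u, v) = exp(corr(u, v)) from standardized series; fully connected.

    Zero-variance vertices get correlation 0 with every other vertex (edge
    strength 1) so the label map stays total; the diagonal is exp(1)
    throughout.
    """
    if not fld.standardized:
        raise ValueError("affinity_matrix requires a standardized field")
    n, T = fld.data.shape
    if n > _DENSE_GUARD:
        warnings.warn(
            f"dense affinity for n={n} vertices needs "
            f"~{8 * n * n / 1e9:.1f} GB",
            stacklevel=2,
        )
    corr = fld.data @ fld.data.T / T
    if fld.zero_variance is not None and fld.zero_variance.any():
        warnings.warn(
            "zero-variance vertices assigned correlation 0 edges",
            stacklevel=2,
        )
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return AffinityGraph(A=np.exp(corr))


def nassoc_score(graph: AffinityGraph, parc: Parcellation | np.ndarray) -> float:
    """Average normalized association of a K-partition (higher is better).

    Score is in (0, 1]; it equals 1 only when between-class affinity is
    zero, so with strictly positive affinities it is < 1 for K >= 2.
    """
    labels = np.asarray(getattr(parc, "labels", parc))
    A = graph.A
    if labels.shape[0] != graph.n:
        raise ValueError(
            f"labels cover {labels.shape[0]} vertices, graph has {graph.n}"
        )
    classes = np.unique(labels)
    declared_k = getattr(parc, "K", None)
    if declared_k is not None and classes.size < declared_k:
        raise ValueError(
            f"empty class: partition declares K={declared_k} but only "
            f"{classes.size} classes are populated"
        )
    row_tot = A.sum(axis=1)
    score = 0.0
    for c in classes:
        idx = labels == c
        if not idx.any():
            raise ValueError(f"empty class {c} in partition")
        within = A[np.ix_(idx, idx)].sum()
        total = row_tot[idx].sum()
        score += within / total
    return float(score / classes.size)


def _yu_shi_discretize(
    X: np.ndarray, K: int, rng: np.random.Generator, max_iter: int = 100
) -> np.ndarray:
    """Rotate the row-normalized spectral embedding toward a 0/1 indicator
    matrix (alternating assignment and orthogonal Procrustes)."""
    n = X.shape[0]
    # init rotation from K maximally spread embedding rows
    R = np.zeros((K, K))
    first = int(rng.integers(n))
    R[:, 0] = X[first]
    c = np.zeros(n)
    for j in range(1, K):
        c += np.abs(X @ R[:, j - 1])
        R[:, j] = X[int(np.argmin(c))]
    last_obj = 0.0
    labels = np.zeros(n, dtype=np.int64)
    for _ in range(max_iter):
        labels = np.argmax(X @ R, axis=1)
        E = np.zeros((n, K))
        E[np.arange(n), labels] = 1.0
        U, sv, Vt = np.linalg.svd(E.T @ X)
        obj = sv.sum()
        R = (U @ Vt).T
        if abs(obj - last_obj) < 1e-10:
            break
        last_obj = obj
    return labels


def ncuts_partition(
    graph: AffinityGraph, K: int, seed: int = 0, n_init: int = 4
) -> Parcellation:
    """Multiclass normalized-cuts partition of an affinity graph.

    Takes the top-K eigenvectors of the symmetrically normalized affinity
    D^{-1/2} A D^{-1/2}, row-normalizes the embedding, and discretizes with
    the rotation-based scheme from ``n_init`` starts, keeping the labeling
    with the highest normalized association; if no start yields K
    non-empty classes, a seeded k-means on the same embedding is used
    instead.  Deterministic given the seed.  The achieved score is
    recorded in the returned provenance.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    n = graph.n
    if K > n:
        raise ValueError(f"K={K} exceeds number of vertices {n}")
    A = graph.A
    if np.ptp(A) < 1e-12:
        warnings.warn(
            "constant affinity graph: partition is non-identifiable; "
            "returning contiguous index blocks",
            stacklevel=2,
        )
        labels = np.minimum(np.arange(n) * K // n, K - 1)
        parc = Parcellation(
            labels=labels,
            K=K,
            provenance={"method": "ncuts", "seed": seed, "degenerate": True},
        )
        parc.provenance["nassoc"] = nassoc_score(graph, parc)
        return parc
    d = A.sum(axis=1)
    dm12 = 1.0 / np.sqrt(d)
    W = dm12[:, None] * A * dm12[None, :]
    # top-K eigenvectors of the normalized affinity (largest eigenvalues)
    _, vec = scipy.linalg.eigh(W, subset_by_index=[n - K, n - 1])
    X = vec[:, ::-1]
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    X = X / np.maximum(norms, 1e-300)
    rng = np.random.default_rng(seed)
    labels, best_score = None, -np.inf
    for _ in range(max(1, n_init)):
        cand = _yu_shi_discretize(X, K, rng)
        if np.unique(cand).size < K:
            continue
        score = nassoc_score(graph, cand)
        if score > best_score:
            labels, best_score = cand, score
    method = "ncuts/yu-shi"
    if labels is None:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        labels = km.fit_predict(X).astype(np.int64)
        method = "ncuts/kmeans-fallback"
    parc = Parcellation(
        labels=labels,
        K=K,
        provenance={"method": method, "seed": seed},
    )
    parc.provenance["nassoc"] = nassoc_score(graph, parc)
    return parc
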