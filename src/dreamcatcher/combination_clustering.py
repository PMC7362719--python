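"""Combination clustering: a weighted evidence-accumulation ensemble.

Many weak 2-means clusterings are run on small random feature subsets (at
most nine features at a time, to sidestep the curse of dimensionality), each
weighted by its mean silhouette value; the weighted co-association
frequencies form a similarity matrix, from which hierarchical clustering
extracts exactly two near-equal clusters: among all dendrogram cuts, the cut
owning the single cluster closest to half the cases wins (ties go to the
highest threshold, i.e. fewest clusters), and everything outside that cluster
becomes the second class.

The 2-means inner loop is a vectorized Lloyd iteration batched over random
restarts; sklearn's KMeans/silhouette serve as independent oracles in the
test-suite, not as the execution path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

__all__ = [
    "EnsembleConfig", "SubClustering", "CoAssocMatrix", "TwoClusterResult",
    "sample_combinations", "subcluster", "accumulate",
    "extract_two_clusters", "run_combination_clustering",
    "two_means", "mean_silhouette",
]

MAX_SUBSET_SIZE = 9


@dataclass
class EnsembleConfig:
    """Ensemble shape: which subset sizes, how many random subsets per size.

    The reference configuration (sizes 2–9, 10 000 combinations each, plus a
    singleton run per feature) enumerates 2475 + 8x10000 = 82 475
    sub-clusterings on the 2475-feature fine-power set.
    """

    subset_sizes: tuple[int, ...] = tuple(range(2, 10))
    combinations: int = 10_000
    include_singletons: bool = True
    restarts: int = 10
    max_iter: int = 100
    linkage: str = "average"  # "average" | "ward"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k < 1 or k > MAX_SUBSET_SIZE for k in self.subset_sizes):
            raise ValueError(f"subset sizes must be within 1..{MAX_SUBSET_SIZE}")
        if self.combinations < 1:
            raise ValueError("combinations must be >= 1")
        if self.linkage not in ("average", "ward"):
            raise ValueError(f"unsupported linkage {self.linkage!r}")


@dataclass
class SubClustering:
    """One piece of ensemble evidence: a binary labeling and its weight."""

    features: np.ndarray
    labels: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError("weight must be finite and >= 0")


@dataclass
class CoAssocMatrix:
    """Symmetric weighted co-association similarity, values in [0,1], diag 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("co-association matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("co-association matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("co-association values must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("co-association diagonal must be 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class TwoClusterResult:
    labels: np.ndarray          # values 1/2 per case
    linkage_method: str
    cut_threshold: float
    pre_merge_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels))
        if present != {1, 2}:
            raise ValueError(f"exactly two labels {{1,2}} required, got {sorted(present)}")

    def size(self, label: int) -> int:
        return int((self.labels == label).sum())


# ---------------------------------------------------------------------------
# subset sampling

def sample_combinations(n_features: int, config: EnsembleConfig) -> list[np.ndarray]:
    """Feature subsets for the ensemble, deterministic under the config seed.

    Singleton subsets for every feature (when enabled), then ``combinations``
    uniform random subsets for each size in ``subset_sizes``.
    """
    if n_features < max(config.subset_sizes):
        raise ValueError(f"{n_features} features cannot support subsets of size "
                         f"{max(config.subset_sizes)}")
    rng = np.random.default_rng(config.seed)
    subsets: list[np.ndarray] = []
    if config.include_singletons:
        subsets.extend(np.array([j]) for j in range(n_features))
    for k in config.subset_sizes:
        for _ in range(config.combinations):
            subsets.append(np.sort(rng.choice(n_features, size=k, replace=False)))
    return subsets


# ---------------------------------------------------------------------------
# base clusterer

def two_means(X: np.ndarray, restarts: int = 10, rng: np.random.Generator | None = None,
              max_iter: int = 100) -> np.ndarray:
    """Best-of-restarts 2-means labels (0/1) via batched Lloyd iterations."""
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cases")
    i = rng.integers(0, n, size=restarts)
    j = rng.integers(0, n - 1, size=restarts)
    j = np.where(j >= i, j + 1, j)
    centers = np.stack([X[i], X[j]], axis=1)  # (R, 2, d)
    labels = np.zeros((restarts, n), dtype=bool)
    for _ in range(max_iter):
        d0 = ((X[None, :, :] - centers[:, 0, None, :]) ** 2).sum(-1)
        d1 = ((X[None, :, :] - centers[:, 1, None, :]) ** 2).sum(-1)
        new_labels = d1 < d0
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c, mask in ((0, ~labels), (1, labels)):
            counts = mask.sum(axis=1)
            empty = counts == 0
            if empty.any():  # re-seed empty clusters from random points
                mask = mask.copy()
                mask[empty, rng.integers(0, n, size=int(empty.sum()))] = True
                counts = mask.sum(axis=1)
            centers[:, c, :] = (mask.astype(float) @ X) / counts[:, None]
    d0 = ((X[None, :, :] - centers[:, 0, None, :]) ** 2).sum(-1)
    d1 = ((X[None, :, :] - centers[:, 1, None, :]) ** 2).sum(-1)
    wcss = np.minimum(d0, d1).sum(axis=1)
    return (d1 < d0)[int(np.argmin(wcss))].astype(int)


def mean_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette with Euclidean distance; singleton clusters score 0."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        return 0.0
    D = cdist(X, X)
    in1 = labels == labels.max()
    n1, n0 = int(in1.sum()), int((~in1).sum())
    s = np.zeros(labels.size)
    for mask, n_own, other in ((in1, n1, ~in1), (~in1, n0, in1)):
        if n_own == 1:
            continue  # silhouette of a singleton cluster is 0
        a = D[np.ix_(mask, mask)].sum(axis=1) / (n_own - 1)
        b = D[np.ix_(mask, other)].mean(axis=1)
        denom = np.maximum(a, b)
        s[mask] = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(s.mean())


def subcluster(X_subset: np.ndarray, config: EnsembleConfig,
               rng: np.random.Generator,
               features: np.ndarray | None = None) -> SubClustering:
    """One weak 2-means clustering on a feature subspace, silhouette-weighted.

    All-identical points yield a single-cluster labeling with weight 0.
    Negative mean silhouettes are clipped to 0 (weights are tallied as
    frequencies).
    """
    X = np.asarray(X_subset, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if features is None:
        features = np.arange(X.shape[1])
    if np.ptp(X, axis=0).max() == 0:
        return SubClustering(features, np.zeros(X.shape[0], dtype=int), 0.0)
    labels = two_means(X, restarts=config.restarts, rng=rng, max_iter=config.max_iter)
    weight = max(0.0, mean_silhouette(X, labels))
    return SubClustering(features, labels, weight)


# ---------------------------------------------------------------------------
# evidence accumulation

def accumulate(subclusterings: Iterable[SubClustering]) -> CoAssocMatrix:
    """Weighted co-association frequencies over the ensemble; diagonal forced to 1."""
    total = 0.0
    acc = None
    for sc in subclusterings:
        if acc is None:
            acc = np.zeros((sc.labels.size, sc.labels.size))
        if sc.weight == 0.0:
            continue
        same = sc.labels[:, None] == sc.labels[None, :]
        acc += sc.weight * same
        total += sc.weight
    if acc is None or total <= 0:
        raise ValueError("ensemble has zero total weight; no evidence to accumulate")
    vals = acc / total
    np.fill_diagonal(vals, 1.0)
    return CoAssocMatrix(vals)


def extract_two_clusters(coassoc: CoAssocMatrix, linkage_method: str = "average",
                         ) -> TwoClusterResult:
    """Cut the co-association dendrogram into two near-equal classes.

    Hierarchical clustering runs on the dissimilarity 1 - coassoc.  Every cut
    (number of clusters 2..n) is scored by how close its best single cluster
    comes to n/2 cases; the winning cluster keeps label 1, the rest become
    label 2.  A flat matrix (all off-diagonal values equal) is rejected as
    non-separable.
    """
    n = coassoc.n
    dissim = 1.0 - coassoc.values
    off = squareform(dissim, checks=False)
    if np.ptp(off) < 1e-12:
        raise ValueError("co-association matrix is flat: cases are not separable")
    Z = linkage(off, method=linkage_method)
    best = None  # (|size - n/2|, n_clusters, flat_labels, winner)
    for n_clusters in range(2, n + 1):
        flat = fcluster(Z, t=n_clusters, criterion="maxclust")
        sizes = np.bincount(flat)[1:]
        winner = int(np.argmax(-np.abs(sizes - n / 2.0))) + 1
        score = abs(int(sizes[winner - 1]) - n / 2.0)
        if best is None or score < best[0]:
            best = (score, n_clusters, flat, winner, tuple(int(s) for s in sizes))
    _, n_clusters, flat, winner, sizes = best
    labels = np.where(flat == winner, 1, 2)
    # the threshold below which the dendrogram has n_clusters clusters
    heights = Z[:, 2]
    cut = float(heights[-(n_clusters - 1)]) if n_clusters > 1 else float("inf")
    return TwoClusterResult(labels, linkage_method, cut, sizes)


def run_combination_clustering(X: np.ndarray, config: EnsembleConfig,
                               ) -> tuple[TwoClusterResult, CoAssocMatrix]:
    """Full ensemble on a (cases x features) matrix; deterministic under seed."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    subsets = sample_combinations(d, config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    acc = np.zeros((n, n))
    total = 0.0
    for subset in subsets:
        sc = subcluster(X[:, subset], config, rng, features=subset)
        if sc.weight > 0:
            acc += sc.weight * (sc.labels[:, None] == sc.labels[None, :])
            total += sc.weight
    if total <= 0:
        raise ValueError("ensemble has zero total weight")
    vals = acc / total
    np.fill_diagonal(vals, 1.0)
    coassoc = CoAssocMatrix(vals)
    return extract_two_clusters(coassoc, config.linkage), coassoc
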