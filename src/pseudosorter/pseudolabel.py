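"""Density-based pseudolabel generation in the latent space.

Local confidence is the KNN density — the inverse of the mean Euclidean
distance to the K nearest neighbors (K = 0.5% of the dataset by default).
High-confidence points are sampled either by taking the densest fraction
outright ("densest") or by a rank-weighted draw without replacement
("weighted") that favors dense points while leaving every point a nonzero
chance. The number of source neurons is estimated with the elbow method on
the inertia curve of K-means++ over k = 2..20, computed on the densest 50%
of the latent space; pseudolabels are then K-means++ assignments on the
sampled subset.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = ["SamplingConfig", "PseudoLabelSet", "knn_density",
           "sample_densest", "sample_weighted", "estimate_k_elbow",
           "assign_pseudolabels", "density_k"]

#: guard against zero distances between coincident points
EPS_DISTANCE = 1e-12


@dataclass
class SamplingConfig:
    """Parameters of density computation, sampling and cluster-count search."""

    k_frac: float = 0.005
    method: str = "weighted"  # or "densest"
    fraction: float = 0.4
    decay_lambda: float = 2.0
    k_search_range: tuple[int, int] = (2, 20)
    elbow_subset_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        if self.method not in ("densest", "weighted"):
            raise ValueError(f"unknown sampling method {self.method!r}")
        lo, hi = self.k_search_range
        if not (2 <= lo <= hi <= 20):
            raise ValueError("k_search_range must sit inside [2, 20]")


@dataclass
class PseudoLabelSet:
    """Sampled dataset indices with their provisional class assignments."""

    indices: np.ndarray
    labels: np.ndarray
    k: int
    fraction: float
    method: str = "weighted"
    seed: int | None = None

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.indices.shape != self.labels.shape:
            raise ValueError("indices and labels disagree on n")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("indices must be unique")
        if self.labels.size and (self.labels.min() < 0
                                 or self.labels.max() >= self.k):
            raise ValueError("labels outside [0, k)")

    def __len__(self) -> int:
        return len(self.indices)


def density_k(n: int, k_frac: float = 0.005) -> int:
    """Neighborhood size for the KNN density: K = max(1, round(k_frac * n))."""
    return max(1, int(round(k_frac * n)))


def knn_density(latent: np.ndarray, K: int) -> np.ndarray:
    """Inverse mean distance to the K nearest neighbors (self excluded)."""
    latent = np.atleast_2d(np.asarray(latent, dtype=np.float64))
    n = latent.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= K:
        raise ValueError(f"need more than K={K} points, got {n}")
    nn = NearestNeighbors(n_neighbors=K + 1).fit(latent)
    dist, _ = nn.kneighbors(latent)
    mean_dist = dist[:, 1:].mean(axis=1)  # drop the self column
    return 1.0 / np.maximum(mean_dist, EPS_DISTANCE)


def _density_order(density: np.ndarray) -> np.ndarray:
    """Indices by descending density; ties broken by ascending index."""
    return np.argsort(-np.asarray(density, dtype=np.float64), kind="stable")


def sample_densest(density: np.ndarray, fraction: float) -> np.ndarray:
    """The ceil(fraction * n) highest-density indices."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n = len(density)
    m = int(np.ceil(fraction * n))
    return np.sort(_density_order(density)[:m])


def sample_weighted(density: np.ndarray, fraction: float,
                    decay_lambda: float = 2.0,
                    seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Rank-weighted sampling without replacement.

    Weight w_i = exp(-decay_lambda * r_i) with r_i the density rank of point
    i normalized to [0, 1] (0 = densest). Rank-based weights are invariant
    to the density scale and keep a nonzero tail: with the default lambda = 2
    the densest point is ~e^2 ≈ 7.4x more likely than the sparsest per draw,
    biasing toward cluster cores without starving sparsely embedded classes.
    Exactly ceil(fraction * n) unique indices are returned.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    density = np.asarray(density, dtype=np.float64)
    n = len(density)
    m = int(np.ceil(fraction * n))
    if m >= n:
        return np.arange(n, dtype=np.int64)
    order = _density_order(density)
    ranks = np.empty(n, dtype=np.float64)
    ranks[order] = np.arange(n)
    r = ranks / max(n - 1, 1)
    w = np.exp(-decay_lambda * r)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    # exponential-race trick == successive weighted draws without replacement
    keys = rng.exponential(1.0, size=n) / w
    chosen = np.argpartition(keys, m)[:m]
    return np.sort(chosen).astype(np.int64)


def estimate_k_elbow(latent_subset: np.ndarray,
                     k_range: tuple[int, int] = (2, 20),
                     seed: int | None = 0,
                     n_restarts: int = 3) -> int:
    """Elbow estimate of the cluster count.

    Runs K-means++ for each k in ``k_range`` (inertia averaged over
    ``n_restarts`` seeded restarts) and returns the k whose point on the
    normalized inertia curve lies farthest from the chord joining the
    curve's endpoints (Kneedle-style maximum chord distance). The result is
    clamped to ``k_range``, itself limited to [2, 20].
    """
    latent_subset = np.atleast_2d(np.asarray(latent_subset, dtype=np.float64))
    lo, hi = int(k_range[0]), int(k_range[1])
    lo = max(2, lo)
    hi = min(20, hi)
    if hi < lo:
        raise ValueError("empty k range after clamping to [2, 20]")
    n = latent_subset.shape[0]
    if n <= hi:
        raise ValueError(f"need more than {hi} points, got {n}")
    ks = np.arange(lo, hi + 1)
    inertias = np.empty(ks.size)
    for i, k in enumerate(ks):
        km = KMeans(n_clusters=int(k), init="k-means++",
                    n_init=n_restarts, random_state=seed)
        km.fit(latent_subset)
        inertias[i] = km.inertia_
    if ks.size == 1:
        return int(ks[0])
    # normalize both axes to [0, 1] and measure distance to the chord
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    span = inertias[0] - inertias[-1]
    y = (inertias - inertias[-1]) / (span if span != 0 else 1.0)
    # chord from (0, y[0]) to (1, y[-1]) in normalized coordinates is the
    # line y = y[0] + (y[-1]-y[0]) x; perpendicular distance up to a constant:
    d = np.abs((y[-1] - y[0]) * x - y + y[0])
    return int(ks[int(np.argmax(d))])


def assign_pseudolabels(latent: np.ndarray, indices: np.ndarray, k: int,
                        seed: int | None = 0, fraction: float | None = None,
                        method: str = "weighted",
                        max_restarts: int = 5) -> PseudoLabelSet:
    """K-means++ class assignments on the sampled latent rows.

    All k classes must come out non-empty; otherwise the clustering is
    restarted with a shifted seed up to ``max_restarts`` times before the
    last result is accepted.
    """
    latent = np.atleast_2d(np.asarray(latent, dtype=np.float64))
    indices = np.asarray(indices, dtype=np.int64)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(indices) < k:
        raise ValueError(f"need at least k={k} sampled points, "
                         f"got {len(indices)}")
    pts = latent[indices]
    base = 0 if seed is None else int(seed)
    labels = None
    for attempt in range(max_restarts + 1):
        km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                    random_state=base + attempt)
        labels = km.fit_predict(pts)
        if len(np.unique(labels)) == k:
            break
        logger.warning("empty pseudoclass, restart %d", attempt + 1)
    if fraction is None:
        fraction = len(indices) / max(len(latent), 1)
    return PseudoLabelSet(indices=indices, labels=labels, k=k,
                          fraction=fraction, method=method, seed=seed)
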