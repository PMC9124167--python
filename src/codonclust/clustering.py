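"""K-means partitioning of genes in (f(A2), f(T2)) space.

Each gene of a genome is a point (f(A2), f(T2)). K-means (Lloyd's
algorithm, k-means++ seeding, best of ``n_restarts`` by inertia) is run
for K = 2..9 and each solution is scored by the mean silhouette
coefficient; the silhouette-optimal K is reported. Independently of the
optimal K, the K = 2 solution defines the two unequal gene groups: the
cluster with fewer genes is SMALL (on a size tie, the cluster whose
centroid has the higher f(T2), which is how the small cluster presents
empirically).

Both features already live on the same [0, 1] scale, so no rescaling is
applied before clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20170326
DEFAULT_N_RESTARTS = 50
DEFAULT_K_RANGE = range(2, 10)

SMALL = "SMALL"
LARGE = "LARGE"


@dataclass
class KMeansResult:
    k: int
    labels: np.ndarray  # (n,) int in [0, k)
    centroids: np.ndarray  # (k, 2)
    inertia: float
    seed: int
    n_restarts: int


@dataclass
class SilhouetteProfile:
    """Mean silhouette per evaluated K and the argmax (ties -> smaller K)."""

    per_k: dict[int, float]
    optimal_k: int

    def to_dict(self) -> dict[str, float | int]:
        out: dict[str, float | int] = {str(k): v for k, v in sorted(self.per_k.items())}
        out["optimal_k"] = self.optimal_k
        return out


@dataclass
class GenomeClusteringResult:
    """Per-genome clustering outcome: optimal K plus the K=2 small/large split."""

    genome_id: str
    optimal_k: int
    two_cluster_labels: np.ndarray  # (n,) of SMALL/LARGE
    small_size: int
    large_size: int
    centroid_small: np.ndarray
    centroid_large: np.ndarray
    silhouette_profile: SilhouetteProfile | None = None
    gene_ids: list[str] = field(default_factory=list)


def _n_distinct(points: np.ndarray) -> int:
    return np.unique(points, axis=0).shape[0]


def kmeans(
    points: np.ndarray,
    k: int,
    seed: int = DEFAULT_SEED,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> KMeansResult:
    """Best-of-restarts K-means with k-means++ initialization.

    Deterministic given ``seed``; raises on fewer distinct points than k.
    """
    points = np.asarray(points, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if _n_distinct(points) < k:
        raise ValueError(f"degenerate input: fewer than {k} distinct points")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        random_state=seed % (2**32),
        algorithm="lloyd",
        tol=1e-10,
    ).fit(points)
    return KMeansResult(
        k=k,
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def silhouette_mean(
    points: np.ndarray,
    labels: np.ndarray,
    subsample_cap: int | None = None,
    seed: int = DEFAULT_SEED,
) -> float:
    """Mean silhouette coefficient (Rousseeuw definition, Euclidean).

    s(i) = (b - a) / max(a, b) with a(i) the mean intra-cluster distance
    (excluding self) and b(i) the smallest mean distance to another
    cluster; s = 0 for singleton clusters and when a = b = 0. With
    ``subsample_cap`` set, at most that many points (seeded draw without
    replacement) enter the computation — an approximation switch for very
    large gene sets, off by default.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    if subsample_cap is not None and points.shape[0] > subsample_cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(points.shape[0], size=subsample_cap, replace=False)
        if np.unique(labels[idx]).size < 2:  # keep at least two clusters
            idx = np.arange(points.shape[0])
        points, labels = points[idx], labels[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = silhouette_samples(points, labels, metric="euclidean")
    return float(np.mean(np.nan_to_num(vals)))


def _argmax_smallest_k(per_k: dict[int, float]) -> int:
    """Argmax over K with ties broken toward the smaller K (parsimony)."""
    best_k, best_s = None, -np.inf
    for k in sorted(per_k):
        if per_k[k] > best_s:
            best_k, best_s = k, per_k[k]
    assert best_k is not None
    return best_k


def select_optimal_k(
    points: np.ndarray,
    k_range: range | list[int] = DEFAULT_K_RANGE,
    seed: int = DEFAULT_SEED,
    n_restarts: int = DEFAULT_N_RESTARTS,
    subsample_cap: int | None = None,
) -> SilhouetteProfile:
    """Survey K over ``k_range`` and pick the silhouette-optimal one.

    Infeasible Ks (more clusters than distinct points) are skipped with a
    warning rather than aborting the genome.
    """
    points = np.asarray(points, dtype=float)
    distinct = _n_distinct(points)
    per_k: dict[int, float] = {}
    for k in k_range:
        if k > distinct:
            logger.warning("skipping K=%d: only %d distinct points", k, distinct)
            continue
        res = kmeans(points, k, seed=seed, n_restarts=n_restarts)
        per_k[k] = silhouette_mean(points, res.labels, subsample_cap=subsample_cap, seed=seed)
    if not per_k:
        raise ValueError("no feasible K in range")
    return SilhouetteProfile(per_k=per_k, optimal_k=_argmax_smallest_k(per_k))


def designate_small_large(
    k2_result: KMeansResult,
    genome_id: str = "",
    gene_ids: list[str] | None = None,
    optimal_k: int | None = None,
    silhouette_profile: SilhouetteProfile | None = None,
) -> GenomeClusteringResult:
    """Name the two K=2 clusters: fewer genes -> SMALL.

    On an exact size tie the cluster with the higher centroid f(T2) is
    SMALL, matching the empirical signature of the small cluster.
    """
    if k2_result.k != 2:
        raise ValueError("small/large designation requires a K=2 result")
    sizes = np.bincount(k2_result.labels, minlength=2)
    if sizes[0] == sizes[1]:
        logger.info("size tie in %s: breaking by centroid f(T2)", genome_id or "genome")
        small_idx = int(np.argmax(k2_result.centroids[:, 1]))
    else:
        small_idx = int(np.argmin(sizes))
    names = np.where(k2_result.labels == small_idx, SMALL, LARGE)
    return GenomeClusteringResult(
        genome_id=genome_id,
        optimal_k=optimal_k if optimal_k is not None else 2,
        two_cluster_labels=names,
        small_size=int(sizes[small_idx]),
        large_size=int(sizes[1 - small_idx]),
        centroid_small=k2_result.centroids[small_idx],
        centroid_large=k2_result.centroids[1 - small_idx],
        silhouette_profile=silhouette_profile,
        gene_ids=list(gene_ids) if gene_ids is not None else [],
    )


def cluster_genome(
    points: np.ndarray,
    gene_ids: list[str],
    genome_id: str = "",
    k_range: range | list[int] = DEFAULT_K_RANGE,
    seed: int = DEFAULT_SEED,
    n_restarts: int = DEFAULT_N_RESTARTS,
    subsample_cap: int | None = None,
) -> GenomeClusteringResult:
    """Full per-genome clustering: silhouette K-survey plus K=2 split."""
    profile = select_optimal_k(
        points, k_range=k_range, seed=seed, n_restarts=n_restarts, subsample_cap=subsample_cap
    )
    k2 = kmeans(points, 2, seed=seed, n_restarts=n_restarts)
    return designate_small_large(
        k2,
        genome_id=genome_id,
        gene_ids=gene_ids,
        optimal_k=profile.optimal_k,
        silhouette_profile=profile,
    )
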