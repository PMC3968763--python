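"""Cluster raters by their beauty-rating profiles and derive stimulus sets.

Participants are points in image-rating space (one dimension per image);
k-means with Euclidean distance groups them into preference clusters. For
each cluster, the 15 images with the best (lowest) and worst (highest)
cluster-mean ratings become the "most beautiful" / "least beautiful"
adaptor sets and the 60 mid-ranked remaining images the evaluation set,
mirroring the adaptation-experiment design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .ratings import RatingMatrix

logger = logging.getLogger(__name__)

MIN_CLUSTER_SIZE = 4  # experimental feasibility floor
K_RANGE = range(2, 11)


@dataclass
class ClusterSolution:
    k: int
    assignment: pd.Series  # participant id -> cluster id (0-based)
    centroids: np.ndarray  # (k, n_images)
    images: list
    wss: float
    diagnostics: pd.DataFrame | None = None  # per-k WSS / BIC / Dunn
    warnings_: list[str] = field(default_factory=list)

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def feasible(self, min_size: int = MIN_CLUSTER_SIZE) -> bool:
        return bool((self.cluster_sizes >= min_size).all())


@dataclass
class AdaptorSets:
    """Per-cluster adaptor and evaluation image sets (pairwise disjoint)."""

    cluster: int
    most_beautiful: list
    least_beautiful: list
    evaluation: list


def _kmeans_bic(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Spherical-Gaussian BIC for a k-means solution.

    Assumes k spherical Gaussian components with a shared variance
    sigma^2 = WSS / (d * (n - k)):  BIC = n*d*ln(sigma^2) + k*(d+1)*ln(n)
    (lower is better).
    """
    n, d = X.shape
    k = centroids.shape[0]
    wss = float(((X - centroids[labels]) ** 2).sum())
    if n <= k or wss <= 0:
        return float("-inf")
    sigma2 = wss / (d * (n - k))
    return n * d * np.log(sigma2) + k * (d + 1) * np.log(n)


def _dunn_index(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Minimum inter-centroid distance over maximum intra-cluster diameter."""
    k = centroids.shape[0]
    inter = np.inf
    for a in range(k):
        for b in range(a + 1, k):
            inter = min(inter, float(np.linalg.norm(centroids[a] - centroids[b])))
    diam = 0.0
    for c in range(k):
        pts = X[labels == c]
        if len(pts) > 1:
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            diam = max(diam, float(np.sqrt(d2.max())))
    if diam == 0:
        return float("inf") if inter > 0 else float("nan")
    return inter / diam


def cluster_raters(
    m: RatingMatrix,
    k: int,
    seed: int = 0,
    n_restarts: int = 100,
    compute_diagnostics: bool = True,
) -> ClusterSolution:
    """k-means over participants in image-rating space.

    Seeded k-means++ with ``n_restarts`` restarts, best within-cluster sum
    of squares kept; deterministic given ``seed``. Diagnostics (WSS, BIC,
    Dunn index) are populated for k = 2..10 where feasible.
    """
    P = m.n_participants
    if not (2 <= k <= min(10, P - 1)):
        raise ValueError(f"k={k} infeasible for {P} participants (need 2 <= k <= min(10, P-1))")
    X = m.ratings.to_numpy(dtype=float)
    warns: list[str] = []
    if np.allclose(X.std(axis=0), 0):
        warns.append("identical raters: cluster separation is degenerate")
        logger.warning(warns[-1])

    def _fit(kk: int) -> KMeans:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns on duplicate points
            return KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed).fit(X)

    km = _fit(k)
    assignment = pd.Series(km.labels_, index=m.ratings.index, name="cluster")
    sizes = assignment.value_counts()
    if (sizes < MIN_CLUSTER_SIZE).any():
        warns.append(
            f"clusters below the minimum feasible size of {MIN_CLUSTER_SIZE}: "
            f"{sorted(sizes[sizes < MIN_CLUSTER_SIZE].index.tolist())}"
        )
    diag = None
    if compute_diagnostics:
        rows = []
        for kk in K_RANGE:
            if kk > P - 1:
                break
            km_k = km if kk == k else _fit(kk)
            rows.append(
                {
                    "k": kk,
                    "wss": float(km_k.inertia_),
                    "bic": _kmeans_bic(X, km_k.labels_, km_k.cluster_centers_),
                    "dunn": _dunn_index(X, km_k.labels_, km_k.cluster_centers_),
                }
            )
        diag = pd.DataFrame(rows).set_index("k")
    return ClusterSolution(
        k=k,
        assignment=assignment,
        centroids=km.cluster_centers_,
        images=m.images,
        wss=float(km.inertia_),
        diagnostics=diag,
        warnings_=warns,
    )


def cluster_mean_ratings(m: RatingMatrix, sol: ClusterSolution) -> pd.DataFrame:
    """Arithmetic mean rating per image for each cluster (clusters x images)."""
    aligned = sol.assignment.reindex(m.ratings.index)
    if aligned.isna().any():
        raise ValueError("cluster solution does not cover all participants in the matrix")
    return m.ratings.groupby(aligned).mean()


def select_adaptor_sets(
    means: pd.DataFrame,
    n_adapt: int = 15,
    n_eval: int = 60,
) -> dict[int, AdaptorSets]:
    """Pick per-cluster adaptor and evaluation sets from cluster-mean ratings.

    Images are ranked by cluster-mean rating ascending (1 = most beautiful),
    ties broken by image id for determinism. The first ``n_adapt`` are the
    most-beautiful adaptors, the last ``n_adapt`` the least-beautiful ones,
    and the evaluation set is the ``n_eval`` images centered in the ranking
    of the remaining (non-adaptor) images.
    """
    n_images = means.shape[1]
    if n_images < 2 * n_adapt + n_eval:
        raise ValueError(
            f"{n_images} images cannot supply {n_adapt}+{n_adapt} adaptors and {n_eval} evaluation images"
        )
    out: dict[int, AdaptorSets] = {}
    for c in means.index:
        order = means.loc[c].reset_index()
        order.columns = ["image_id", "mean_rating"]
        order = order.sort_values(["mean_rating", "image_id"], kind="mergesort")
        ranked = order["image_id"].tolist()
        most = ranked[:n_adapt]
        least = ranked[-n_adapt:]
        middle = ranked[n_adapt:-n_adapt]
        start = (len(middle) - n_eval) // 2
        evaluation = middle[start : start + n_eval]
        out[int(c)] = AdaptorSets(
            cluster=int(c),
            most_beautiful=most,
            least_beautiful=least,
            evaluation=evaluation,
        )
    return out
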