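"""Hierarchical trees, K-means with Davies-Bouldin K-estimation, and
mixture-model time-course profile clustering.

The sample condition tree uses Pearson correlation similarity
(d = 1 - r) with UPGMA (average linkage), exportable to Newick.  K for
K-means is chosen by minimising the Davies-Bouldin index over a range.
Time-course profile clustering fits spherical-covariance Gaussian
mixtures by EM with the component count selected by BIC - a transparent
stand-in for HMM-based time-course clustering packages that preserves
their contract (at most ``max_components`` clusters, data-driven count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score
from sklearn.mixture import GaussianMixture

from .core_io import ExpressionMatrix, SampleDesign


# ---------------------------------------------------------------------------
# Distances and hierarchical clustering


def pearson_distance(profiles: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise d = 1 - Pearson r between rows; d in [0, 2], zero diagonal."""
    if isinstance(profiles, pd.DataFrame):
        names = list(profiles.index)
        values = profiles.to_numpy(dtype=float)
    else:
        values = np.asarray(profiles, dtype=float)
        names = [str(i) for i in range(values.shape[0])]
    if values.shape[1] < 3:
        raise ValueError("need at least 3 features per item")
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant profiles have no correlation: {bad[:5]}")
    r = np.corrcoef(values)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class Dendrogram:
    """UPGMA merge tree with labelled leaves."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    def cophenetic(self) -> pd.DataFrame:
        dense = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(dense, index=self.labels, columns=self.labels)

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def sibling_pairs(self) -> list[tuple[str, str]]:
        """Leaf pairs merged directly with each other."""
        pairs = []
        n = len(self.labels)
        for a, b, _, _ in self.linkage:
            if a < n and b < n:
                pairs.append((self.labels[int(a)], self.labels[int(b)]))
        return pairs

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        inner = f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)})"
        return inner + ";"


def hierarchical_average_linkage(
    distance: np.ndarray, labels: Sequence[str] | None = None
) -> Dendrogram:
    """UPGMA over a symmetric distance matrix.

    scipy breaks merge ties by the lowest pair index, which makes the
    tree deterministic for a given matrix.
    """
    distance = np.asarray(distance, dtype=float)
    n = distance.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    if labels is None:
        labels = [str(i) for i in range(n)]
    condensed = squareform(distance, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=linkage, labels=list(labels))


def condition_tree(
    matrix: ExpressionMatrix, design: SampleDesign, log_first: bool = True
) -> Dendrogram:
    """Sample tree over replicate-averaged (condition, time) profiles."""
    from .preprocess import summarize_replicates

    averaged = summarize_replicates(matrix, design, statistic="mean")
    values = averaged.values
    if log_first:
        values = np.log2(np.clip(values, 1e-12, None))
    dist = pearson_distance(values.T)
    return hierarchical_average_linkage(dist, labels=list(averaged.data.columns))


# ---------------------------------------------------------------------------
# K-means with Davies-Bouldin K selection


@dataclass
class ClusterResult:
    labels: pd.Series  # item -> cluster label in 1..k
    k: int
    centroids: np.ndarray
    scores: dict = field(default_factory=dict)

    def members(self, label: int) -> list:
        return list(self.labels.index[self.labels == label])


def kmeans_with_db(
    data: np.ndarray | pd.DataFrame,
    k_range: Sequence[int],
    seed: int = 0,
    restarts: int = 10,
) -> ClusterResult:
    """Best-of-restarts Euclidean K-means for each K; K chosen by the
    minimal Davies-Bouldin index.  Deterministic given the seed."""
    if isinstance(data, pd.DataFrame):
        index = data.index
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        index = pd.RangeIndex(values.shape[0])
    k_range = [k for k in k_range if 1 < k <= values.shape[0]]
    if not k_range:
        raise ValueError("no feasible K in k_range")
    best: tuple[float, int, KMeans] | None = None
    db_by_k: dict[int, float] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels = km.fit_predict(values)
        if len(np.unique(labels)) < 2:
            continue
        db = davies_bouldin_score(values, labels)
        db_by_k[k] = db
        if best is None or db < best[0]:
            best = (db, k, km)
    if best is None:
        raise ValueError("Davies-Bouldin undefined for every candidate K")
    db, k, km = best
    return ClusterResult(
        labels=pd.Series(km.labels_ + 1, index=index, name="cluster"),
        k=k,
        centroids=km.cluster_centers_,
        scores={"davies_bouldin": db, "db_by_k": db_by_k, "inertia": km.inertia_},
    )


def kmeans_fixed_k(
    data: np.ndarray | pd.DataFrame, k: int, seed: int = 0, restarts: int = 10
) -> ClusterResult:
    if isinstance(data, pd.DataFrame):
        index = data.index
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        index = pd.RangeIndex(values.shape[0])
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    km.fit(values)
    return ClusterResult(
        labels=pd.Series(km.labels_ + 1, index=index, name="cluster"),
        k=k,
        centroids=km.cluster_centers_,
        scores={"inertia": km.inertia_},
    )


# ---------------------------------------------------------------------------
# Mixture-model profile clustering


def mixture_profile_cluster(
    profiles: np.ndarray | pd.DataFrame,
    max_components: int = 8,
    restarts: int = 10,
    seed: int = 0,
) -> ClusterResult:
    """EM-fitted spherical Gaussian mixture over profile space.

    The component count is selected by BIC over 1..max_components; items
    are assigned to their maximum-responsibility component.  With fewer
    profiles than components the candidate count is reduced.
    """
    if isinstance(profiles, pd.DataFrame):
        index = profiles.index
        values = profiles.to_numpy(dtype=float)
    else:
        values = np.asarray(profiles, dtype=float)
        index = pd.RangeIndex(values.shape[0])
    if values.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if np.allclose(values, values[0]):
        # all profiles identical: a single degenerate component
        return ClusterResult(
            labels=pd.Series(1, index=index, name="cluster"),
            k=1,
            centroids=values[:1].copy(),
            scores={"bic_by_k": {1: float("nan")}},
        )
    max_k = min(max_components, values.shape[0])
    best: tuple[float, GaussianMixture] | None = None
    bic_by_k: dict[int, float] = {}
    for k in range(1, max_k + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="spherical",
            n_init=restarts,
            random_state=seed,
            reg_covar=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(values)
        bic = gm.bic(values)
        bic_by_k[k] = float(bic)
        if best is None or bic < best[0]:
            best = (bic, gm)
    assert best is not None
    _, gm = best
    raw_labels = gm.predict(values)
    used = np.unique(raw_labels)
    remap = {old: new + 1 for new, old in enumerate(used)}
    labels = pd.Series([remap[l] for l in raw_labels], index=index, name="cluster")
    if len(used) < gm.n_components:
        warnings.warn(
            f"pruned {gm.n_components - len(used)} empty mixture components",
            stacklevel=2,
        )
    return ClusterResult(
        labels=labels,
        k=len(used),
        centroids=gm.means_[used],
        scores={"bic_by_k": bic_by_k},
    )


# ---------------------------------------------------------------------------
# Limb-bud K = 3 partition


@dataclass
class LimbBudPartition:
    result: ClusterResult
    high_clusters: list[int]
    fraction_high: float
    fraction_low: float


def limb_bud_partition(
    standardized: pd.DataFrame,
    injury_columns: Sequence[str],
    bud_columns: Sequence[str],
    seed: int = 0,
    restarts: int = 10,
    k: int = 3,
) -> LimbBudPartition:
    """K-means with fixed K over standardized profiles including limb-bud
    columns; a cluster is limb-bud-high when its centroid's mean limb-bud
    feature exceeds the centroid's mean over the injury time course."""
    bud_columns = list(bud_columns)
    injury_columns = list(injury_columns)
    if not bud_columns or any(c not in standardized.columns for c in bud_columns):
        raise ValueError("limb-bud columns missing from the standardized matrix")
    cols = injury_columns + bud_columns
    data = standardized[cols]
    result = kmeans_fixed_k(data, k=min(k, len(data)), seed=seed, restarts=restarts)
    n_injury = len(injury_columns)
    high = []
    for label in range(1, result.k + 1):
        centroid = result.centroids[label - 1]
        if centroid[n_injury:].mean() > centroid[:n_injury].mean():
            high.append(label)
    in_high = result.labels.isin(high)
    return LimbBudPartition(
        result=result,
        high_clusters=high,
        fraction_high=float(in_high.mean()),
        fraction_low=float((~in_high).mean()),
    )
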