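"""Cluster targets by embedding similarity; quantify bootstrap stability.

Louvain community detection runs on a dense weighted graph whose edge
weights are the positive part of the pairwise cosine similarities
(negative similarities carry no affinity and are set to zero); k-means
operates on the embedding vectors and hierarchical clustering on cosine
distances.  Because semantic spaces rarely have sharp thematic borders,
no "optimal" number of clusters is estimated — instead
:func:`cluster_stability` reruns the clustering on bootstrap samples of
the targets and reports, for every pair, the proportion of reruns in
which the two were co-assigned, aggregated to cluster level by the
reference partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StateError, UsageError
from .study import AssociationStudy

logger = logging.getLogger(__name__)

CLUSTER_METHODS = ("louvain", "kmeans", "hierarchical")


@dataclass
class SimilarityMatrix:
    """Symmetric cosine-similarity matrix over labelled targets."""

    labels: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def cosine_similarity_matrix(
    labels: list[str], vectors: np.ndarray
) -> SimilarityMatrix:
    """Pairwise cosine similarities; all-zero vectors are dropped."""
    from sklearn.metrics.pairwise import cosine_similarity

    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    keep = norms > 0
    if not keep.all():
        dropped = [l for l, k in zip(labels, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-vector target(s): "
            + ", ".join(dropped[:10]),
            stacklevel=2,
        )
        labels = [l for l, k in zip(labels, keep) if k]
        vectors = vectors[keep]
    sims = np.clip(cosine_similarity(vectors), -1.0, 1.0)
    np.fill_diagonal(sims, 1.0)
    return SimilarityMatrix(labels=list(labels), values=sims)


def study_similarity(study: AssociationStudy) -> SimilarityMatrix:
    if study.embedding is None:
        raise StateError("no embedding present; call embed_targets first")
    return cosine_similarity_matrix(study.embedding.labels, study.embedding.vectors)


def _louvain_labels(
    sims: np.ndarray, resolution: float, seed: int | None
) -> np.ndarray:
    """Louvain on the positive-part similarity graph (no self-loops)."""
    import networkx as nx

    n = sims.shape[0]
    weights = np.maximum(sims, 0.0)
    np.fill_diagonal(weights, 0.0)
    graph = nx.from_numpy_array(weights)
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed if seed is not None else 0
    )
    labels = np.empty(n, dtype=int)
    for idx, members in enumerate(communities):
        labels[list(members)] = idx
    return labels


def _cluster_vectors(
    vectors: np.ndarray,
    method: str,
    n_clusters: int | None,
    resolution: float,
    linkage: str,
    seed: int | None,
) -> np.ndarray:
    n = vectors.shape[0]
    if method == "louvain":
        if n_clusters is not None:
            raise UsageError(
                "louvain determines the number of clusters itself; do not "
                "pass n_clusters (use resolution to steer granularity)"
            )
        sims = cosine_similarity_matrix([str(i) for i in range(n)], vectors)
        return _louvain_labels(sims.values, resolution, seed)
    if n_clusters is None:
        raise UsageError(f"method={method!r} requires n_clusters")
    if n_clusters > n:
        raise UsageError(f"n_clusters={n_clusters} exceeds number of targets {n}")
    if method == "kmeans":
        from sklearn.cluster import KMeans

        model = KMeans(
            n_clusters=n_clusters,
            n_init=10,
            random_state=seed if seed is not None else 0,
        )
        return model.fit_predict(vectors)
    if method == "hierarchical":
        from sklearn.cluster import AgglomerativeClustering
        from sklearn.metrics.pairwise import cosine_distances

        model = AgglomerativeClustering(
            n_clusters=n_clusters, metric="precomputed", linkage=linkage
        )
        return model.fit_predict(cosine_distances(vectors))
    raise UsageError(f"method must be one of {CLUSTER_METHODS}")


def _canonical_labels(raw: np.ndarray, labels: list[str]) -> pd.Series:
    """Relabel clusters 1..K by descending size (ties: alphabetical head)."""
    series = pd.Series(raw, index=labels)
    order = sorted(
        series.groupby(series).groups.items(),
        key=lambda kv: (-len(kv[1]), min(kv[1])),
    )
    mapping = {old: new + 1 for new, (old, _) in enumerate(order)}
    return series.map(mapping)


def cluster_targets(
    study: AssociationStudy,
    method: str = "louvain",
    n_clusters: int | None = None,
    resolution: float = 1.0,
    linkage: str = "complete",
    seed: int | None = None,
) -> AssociationStudy:
    """Assign each embedded target a cluster label (targets.cluster).

    Clusters are numbered 1..K by descending size for stable, readable
    labels.  Targets without an embedding row (dropped at count-matrix
    construction) get a missing label.
    """
    if method not in CLUSTER_METHODS:
        raise UsageError(f"method must be one of {CLUSTER_METHODS}")
    if study.embedding is None:
        raise StateError("no embedding present; call embed_targets first")
    raw = _cluster_vectors(
        study.embedding.vectors, method, n_clusters, resolution, linkage, seed
    )
    assignment = _canonical_labels(raw, study.embedding.labels)
    out = study.copy()
    out.targets = out.targets.copy()
    out.targets["cluster"] = out.targets["target"].map(assignment).astype("Int64")
    out.meta["clustering"] = {
        "method": method,
        "n_clusters": n_clusters,
        "resolution": resolution,
        "seed": seed,
    }
    return out


def chance_coassignment(
    n_clusters: int | None = None, probs: np.ndarray | None = None
) -> float:
    """Expected same-cluster co-assignment rate under random assignment.

    If two targets are assigned independently to cluster c with
    probability p_c, they land together with probability sum_c p_c^2 —
    1/K for K equiprobable clusters.  This is the chance level against
    which bootstrap stability proportions should be read.
    """
    if probs is None:
        if n_clusters is None or n_clusters < 1:
            raise UsageError("pass n_clusters >= 1 or an explicit probs vector")
        probs = np.full(n_clusters, 1.0 / n_clusters)
    probs = np.asarray(probs, dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise UsageError("cluster probabilities must sum to 1")
    return float((probs**2).sum())


@dataclass
class StabilityResult:
    """Bootstrap co-assignment proportions, pairwise and per cluster.

    ``pairwise``: for each target pair, the share of bootstrap reruns
    (among those where both were sampled) that put them in the same
    cluster; NaN where a pair never co-occurred.  ``cluster_level``:
    those proportions averaged within/between the reference clusters;
    the diagonal is each cluster's stability, ideally 1.
    """

    pairwise: pd.DataFrame
    cluster_level: pd.DataFrame
    n_bootstrap: int
    seed: int | None
    method: str
    params: dict


def cluster_stability(
    study: AssociationStudy,
    method: str | None = None,
    n_bootstrap: int = 100,
    seed: int | None = None,
    n_clusters: int | None = None,
    resolution: float | None = None,
    linkage: str | None = None,
) -> StabilityResult:
    """Bootstrap the targets and rerun the clustering to assess stability.

    Each rerun samples N targets with replacement, reduces to the unique
    sampled set (duplicate nodes would distort modularity), re-clusters
    that subset, and records same/different cluster for every co-sampled
    pair.  Aggregation to cluster level uses the reference (full-data)
    assignment in ``targets.cluster``, so no bootstrap-to-reference label
    matching is needed.
    """
    if n_bootstrap < 1:
        raise UsageError("n_bootstrap must be >= 1")
    if study.embedding is None:
        raise StateError("no embedding present; call embed_targets first")
    targets = study.targets
    if targets is None or "cluster" not in targets.columns:
        raise StateError("no reference clustering; call cluster_targets first")
    cfg = study.meta.get("clustering", {})
    method = method or cfg.get("method", "louvain")
    n_clusters = n_clusters if n_clusters is not None else cfg.get("n_clusters")
    resolution = resolution if resolution is not None else cfg.get("resolution", 1.0)
    linkage = linkage or cfg.get("linkage", "complete")

    labels = study.embedding.labels
    vectors = study.embedding.vectors
    n = len(labels)
    rng = np.random.default_rng(seed)
    co_sampled = np.zeros((n, n), dtype=float)
    co_assigned = np.zeros((n, n), dtype=float)
    for _ in range(n_bootstrap):
        sampled = np.unique(rng.integers(0, n, size=n))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if method == "louvain":
            sub_k = None
        else:
            if n_clusters is None:
                raise UsageError(f"method={method!r} requires n_clusters")
            sub_k = min(n_clusters, len(sampled))
        sub_labels = _cluster_vectors(
            vectors[sampled], method, sub_k, resolution, linkage, sub_seed
        )
        same = sub_labels[:, None] == sub_labels[None, :]
        grid = np.ix_(sampled, sampled)
        co_sampled[grid] += 1.0
        co_assigned[grid] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        pairwise = co_assigned / co_sampled
    pairwise_df = pd.DataFrame(pairwise, index=labels, columns=labels)

    reference = targets.set_index("target")["cluster"].reindex(labels)
    cluster_ids = sorted(reference.dropna().unique())
    k = len(cluster_ids)
    cluster_level = np.full((k, k), np.nan)
    off_diag = ~np.eye(n, dtype=bool)
    for a, ca in enumerate(cluster_ids):
        for b, cb in enumerate(cluster_ids):
            in_a = (reference == ca).to_numpy()
            in_b = (reference == cb).to_numpy()
            mask = np.outer(in_a, in_b) & off_diag
            vals = pairwise[mask]
            vals = vals[~np.isnan(vals)]
            if vals.size:
                cluster_level[a, b] = vals.mean()
    cluster_level_df = pd.DataFrame(
        cluster_level, index=cluster_ids, columns=cluster_ids
    )
    return StabilityResult(
        pairwise=pairwise_df,
        cluster_level=cluster_level_df,
        n_bootstrap=n_bootstrap,
        seed=seed,
        method=method,
        params={
            "n_clusters": n_clusters,
            "resolution": resolution,
            "linkage": linkage,
        },
    )
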