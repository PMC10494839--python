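"""Partition validity: DBCV, prediction strength, convex indices, entropy, gate.

The gate encodes the framework's decision rule for "a plausible enterotype
partition": the density pair (DBCV > 0 and prediction strength >= 0.8), the
convex pair (silhouette >= 0.5 and Davies-Bouldin <= 0.6), and balance
(every cluster holds >= 5% of the non-noise mass).  A partition counts as
evidence for clusters only when all of them hold at once; among passing
partitions the highest-entropy (most balanced) one is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

from .clustering import Partition

__all__ = [
    "PartitionMetrics",
    "DEFAULT_THRESHOLDS",
    "dbcv",
    "prediction_strength",
    "convex_metrics",
    "partition_entropy",
    "gate",
    "select_best",
    "score_partition",
]

DEFAULT_THRESHOLDS = {
    "dbcv": 0.0,             # strictly positive required
    "prediction_strength": 0.8,
    "silhouette": 0.5,
    "davies_bouldin": 0.6,
    "min_mass": 0.05,
}


@dataclass
class PartitionMetrics:
    dbcv: float | None = None
    prediction_strength: float | None = None
    silhouette: float | None = None
    davies_bouldin: float | None = None
    calinski_harabasz: float | None = None
    entropy: float = 0.0
    min_mass: float = 0.0
    k: int = 0
    pass_density_pair: bool = False
    pass_convex_pair: bool = False
    balanced: bool = False
    pass_all: bool = False


# ---------------------------------------------------------------- DBCV

def _core_dists(D: np.ndarray, members: np.ndarray, m: int) -> np.ndarray:
    """All-points core distance of each cluster member, against its own cluster."""
    sub = D[np.ix_(members, members)]
    nc = members.size
    with np.errstate(divide="ignore"):
        inv = np.where(np.eye(nc, dtype=bool), 0.0, 1.0 / sub) ** m
    s = inv.sum(axis=1)
    with np.errstate(divide="ignore"):
        a = (s / (nc - 1)) ** (-1.0 / m)
    return np.where(np.isfinite(a), a, 0.0)  # coincident points -> core distance 0


def dbcv(X: np.ndarray | None, labels: np.ndarray, *,
         precomputed: np.ndarray | None = None, dim: int | None = None) -> float:
    """Density-Based Cluster Validation index in [-1, 1].

    Per cluster, an all-points core distance defines mutual-reachability
    distances; the cluster's *density sparseness* is the largest edge of the
    mutual-reachability minimum spanning tree restricted to internal nodes
    (degree >= 2), and its *separation* from another cluster is the smallest
    mutual reachability between their internal nodes.  Cluster validity is
    (min separation - sparseness) / max(min separation, sparseness), and the
    index is the cluster-size-weighted sum with noise points counted in n.

    Accepts either coordinates ``X`` (Euclidean distances, ``dim`` inferred)
    or ``precomputed`` distances with an explicit ``dim``.
    """
    labels = np.asarray(labels, dtype=int)
    if precomputed is not None:
        D = np.asarray(precomputed, dtype=float)
        if dim is None:
            raise ValueError("dim is required with precomputed distances")
        m = dim
    else:
        X = np.asarray(X, dtype=float)
        D = squareform(pdist(X))
        m = X.shape[1]
    n = labels.size
    cluster_ids = np.array(sorted(set(labels[labels >= 0])))
    if cluster_ids.size == 0:
        raise ValueError("all points are noise; DBCV is undefined")

    members = {c: np.flatnonzero(labels == c) for c in cluster_ids}
    core = {c: _core_dists(D, members[c], m) if members[c].size > 1 else np.zeros(1)
            for c in cluster_ids}

    sparseness: dict[int, float] = {}
    internal: dict[int, np.ndarray] = {}
    for c in cluster_ids:
        idx = members[c]
        if idx.size < 2:
            sparseness[c] = 0.0
            internal[c] = idx
            continue
        sub = D[np.ix_(idx, idx)]
        a = core[c]
        mr = np.maximum(sub, np.maximum(a[:, None], a[None, :]))
        np.fill_diagonal(mr, 0.0)
        mst = minimum_spanning_tree(mr).toarray()
        adj = (mst > 0) | (mst.T > 0)
        deg = adj.sum(axis=1)
        internal_mask = deg >= 2
        if internal_mask.sum() < 1:
            internal_mask = np.ones(idx.size, dtype=bool)  # tiny-cluster fallback
        edges = np.transpose(np.nonzero(mst))
        internal_edges = [mst[i, j] for i, j in edges
                          if internal_mask[i] and internal_mask[j]]
        sparseness[c] = float(max(internal_edges)) if internal_edges \
            else float(mst.max())
        internal[c] = idx[internal_mask]

    total = 0.0
    for c in cluster_ids:
        idx_c = internal[c]
        a_c = core[c][np.isin(members[c], idx_c)]
        if cluster_ids.size == 1:
            validity = 0.0  # a lone cluster has no separation to speak of
        else:
            seps = []
            for o in cluster_ids:
                if o == c:
                    continue
                idx_o = internal[o]
                a_o = core[o][np.isin(members[o], idx_o)]
                d_co = D[np.ix_(idx_c, idx_o)]
                mr = np.maximum(d_co, np.maximum(a_c[:, None], a_o[None, :]))
                seps.append(mr.min())
            min_sep = float(min(seps))
            denom = max(min_sep, sparseness[c])
            validity = 0.0 if denom == 0 else (min_sep - sparseness[c]) / denom
        total += members[c].size / n * validity
    return float(total)


# --------------------------------------------------- prediction strength

def prediction_strength(X: np.ndarray,
                        clusterer: Callable[[np.ndarray, int], Partition],
                        n_repeats: int = 10, seed: int = 0) -> float:
    """Stability of cluster decision boundaries under 2-fold splitting.

    Per repeat the points are split in half; both halves are clustered; test
    points are classified by the training partition (nearest medoid when the
    clusterer exposes medoids, otherwise the label of the nearest non-noise
    training point).  The repeat's score is the minimum, over test clusters,
    of the fraction of same-cluster pairs that the training classifier also
    co-assigns; test clusters smaller than 2 contribute 1.  Returns the mean
    over repeats.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 20:
        raise ValueError("prediction strength needs at least 20 points")
    rng = np.random.default_rng(seed)
    scores = []
    for r in range(n_repeats):
        perm = rng.permutation(n)
        train, test = perm[: n // 2], perm[n // 2:]
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        p_train = clusterer(X[train], sub_seed)
        p_test = clusterer(X[test], sub_seed)

        medoids = p_train.hyperparams.get("medoids")
        if p_train.method == "pam" and medoids is not None:
            centers = X[train][np.asarray(medoids, dtype=int)]
            d = np.linalg.norm(X[test][:, None, :] - centers[None], axis=2)
            induced = np.argmin(d, axis=1)
        else:
            ok = p_train.labels >= 0
            if not ok.any():
                scores.append(0.0)
                continue
            pool = X[train][ok]
            pool_labels = p_train.labels[ok]
            d = np.linalg.norm(X[test][:, None, :] - pool[None], axis=2)
            induced = pool_labels[np.argmin(d, axis=1)]

        per_cluster = []
        for c in sorted(set(p_test.labels[p_test.labels >= 0])):
            mask = p_test.labels == c
            size = int(mask.sum())
            if size < 2:
                per_cluster.append(1.0)
                continue
            _, counts = np.unique(induced[mask], return_counts=True)
            co = (counts * (counts - 1) // 2).sum()
            per_cluster.append(co / (size * (size - 1) // 2))
        scores.append(min(per_cluster) if per_cluster else 1.0)
    return float(np.mean(scores))


# --------------------------------------------------------- convex metrics

def convex_metrics(X: np.ndarray, labels: np.ndarray
                   ) -> tuple[float | None, float | None, float | None]:
    """Silhouette, Davies-Bouldin and Calinski-Harabasz on non-noise points.

    Undefined (None) when fewer than two clusters remain; an all-coincident
    degenerate input returns silhouette 0 by the zero-denominator convention.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    ok = labels >= 0
    Xo, lo = X[ok], labels[ok]
    if len(set(lo)) < 2:
        return None, None, None
    if np.ptp(Xo, axis=0).max(initial=0.0) == 0.0:
        warnings.warn("all points coincide; silhouette set to 0 by convention")
        return 0.0, 0.0, 0.0
    sil = float(silhouette_score(Xo, lo))
    db = float(davies_bouldin_score(Xo, lo))
    ch = float(calinski_harabasz_score(Xo, lo))
    return sil, db, ch


def partition_entropy(labels: np.ndarray, base: str = "nat") -> float:
    """Shannon entropy of the non-noise cluster mass distribution."""
    labels = np.asarray(labels, dtype=int)
    lab = labels[labels >= 0]
    if lab.size == 0:
        return 0.0
    _, counts = np.unique(lab, return_counts=True)
    p = counts / lab.size
    h = float(-(p * np.log(p)).sum())
    return h / np.log(2.0) if base == "bit" else h


# ----------------------------------------------------------------- gate

def gate(metrics: PartitionMetrics,
         thresholds: dict | None = None) -> PartitionMetrics:
    """Set the pair/balance/pass_all flags from the metric thresholds.

    Comparisons at the thresholds are inclusive except DBCV, which must be
    strictly positive.  A metric that is undefined (None) fails its pair.
    """
    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    m = metrics
    m.pass_density_pair = (
        m.dbcv is not None and m.dbcv > th["dbcv"]
        and m.prediction_strength is not None
        and m.prediction_strength >= th["prediction_strength"])
    m.pass_convex_pair = (
        m.silhouette is not None and m.silhouette >= th["silhouette"]
        and m.davies_bouldin is not None
        and m.davies_bouldin <= th["davies_bouldin"])
    m.balanced = m.min_mass >= th["min_mass"]
    m.pass_all = m.pass_density_pair and m.pass_convex_pair and m.balanced
    return m


def score_partition(X: np.ndarray, p: Partition,
                    ps_clusterer: Callable[[np.ndarray, int], Partition] | None = None,
                    n_repeats: int = 10, seed: int = 0,
                    thresholds: dict | None = None) -> PartitionMetrics:
    """All metrics for one partition in its representation space, gated."""
    m = PartitionMetrics(k=p.k, entropy=partition_entropy(p.labels))
    masses = p.masses
    m.min_mass = float(masses.min()) if masses.size else 0.0
    sil, db, ch = convex_metrics(X, p.labels)
    m.silhouette, m.davies_bouldin, m.calinski_harabasz = sil, db, ch
    if p.k >= 1 and (p.labels >= 0).any():
        sizes = np.bincount(p.labels[p.labels >= 0])
        if (sizes[sizes > 0] >= 2).any():
            m.dbcv = dbcv(X, p.labels)
    if ps_clusterer is not None:
        m.prediction_strength = prediction_strength(X, ps_clusterer,
                                                    n_repeats=n_repeats, seed=seed)
    return gate(m, thresholds)


def select_best(scored: list[tuple[Partition, PartitionMetrics]],
                criterion: str = "pass_all", selection: str = "balance") -> dict:
    """Pick the most balanced partition among those passing the gate.

    ``criterion`` chooses the admission rule: ``pass_all`` (default), or the
    single pairs ``density`` / ``convex``.  ``selection`` ranks the admitted
    partitions: ``balance`` (default) maximizes the normalized entropy
    H / ln k — the entropy criterion made comparable across cluster counts,
    since raw entropy alone always prefers the most-subdivided balanced
    partition — while ``entropy`` maximizes raw H (equivalent whenever the
    candidates share one k).  The verdict is ``clusters-found`` iff some
    partition has pass_all; otherwise ``no plausible partition``.
    """
    if selection not in ("balance", "entropy"):
        raise ValueError(f"unknown selection rule {selection!r}")

    def _rank(m: PartitionMetrics) -> float:
        if selection == "entropy" or m.k < 2:
            return m.entropy
        return m.entropy / np.log(m.k)

    def admitted(m: PartitionMetrics) -> bool:
        if criterion == "pass_all":
            return m.pass_all
        if criterion == "density":
            return m.pass_density_pair and m.balanced
        if criterion == "convex":
            return m.pass_convex_pair and m.balanced
        raise ValueError(f"unknown criterion {criterion!r}")

    passing: dict[bytes, tuple[Partition, PartitionMetrics]] = {}
    for p, m in scored:
        if admitted(m):
            key = p.labels.tobytes()
            if key not in passing or _rank(m) > _rank(passing[key][1]):
                passing[key] = (p, m)
    any_pass_all = any(m.pass_all for _, m in scored)
    report = {
        "verdict": "clusters-found" if any_pass_all else "no plausible partition",
        "criterion": criterion,
        "selection": selection,
        "n_scored": len(scored),
        "n_passing": len(passing),
        "selected": None,
    }
    if passing:
        p, m = max(passing.values(), key=lambda pm: _rank(pm[1]))
        report["selected"] = {"partition": p, "metrics": m, "k": p.k,
                              "entropy": m.entropy, "rank_value": _rank(m)}
    return report
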