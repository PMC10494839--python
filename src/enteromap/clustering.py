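"""Candidate partitions: PAM (k-medoids), spectral clustering, HDBSCAN, and the
driver-genus baseline assignment.

PAM is authored here (BUILD initialization + vectorized SWAP passes) so the
objective can be checked against exhaustive medoid enumeration on small
instances; spectral clustering and HDBSCAN delegate to scikit-learn behind
the same partition contract.  Noise points (HDBSCAN only) carry label -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import HDBSCAN, SpectralClustering
from sklearn.neighbors import kneighbors_graph

from .preprocess import AbundanceTable, DistanceMatrix

__all__ = [
    "Partition",
    "pam",
    "pam_objective",
    "spectral",
    "hdbscan_cluster",
    "assign_by_driver_taxa",
    "sweep_clusterings",
    "DRIVER_GENERA",
]

DRIVER_GENERA = ("Bacteroides", "Prevotella", "Ruminococcus")


@dataclass
class Partition:
    """Cluster labels over one data representation; -1 marks noise."""

    labels: np.ndarray
    method: str
    hyperparams: dict
    representation_id: str = ""
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def k(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    @property
    def masses(self) -> np.ndarray:
        """Fractions of non-noise points per cluster, in label order."""
        lab = self.labels[self.labels >= 0]
        if lab.size == 0:
            return np.array([])
        _, counts = np.unique(lab, return_counts=True)
        return counts / lab.size

    @property
    def noise_fraction(self) -> float:
        return float(np.mean(self.labels < 0))


def _as_distance(rep: np.ndarray | DistanceMatrix) -> tuple[np.ndarray, bool]:
    """Return (square distance matrix, was_precomputed)."""
    if isinstance(rep, DistanceMatrix):
        return rep.values, True
    X = np.asarray(rep, dtype=float)
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(X)), False


def pam_objective(D: np.ndarray, medoids: np.ndarray) -> float:
    """Total distance of every point to its nearest medoid."""
    return float(D[:, medoids].min(axis=1).sum())


def _pam_build(D: np.ndarray, k: int) -> np.ndarray:
    """BUILD: first medoid minimizes total distance; then greedy additions."""
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[:, medoids[0]].copy()
    for _ in range(1, k):
        gains = np.maximum(d_near[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        d_near = np.minimum(d_near, D[:, best])
    return np.array(sorted(medoids))


def pam(rep: np.ndarray | DistanceMatrix, k: int, seed: int = 0,
        max_iter: int = 200, n_restarts: int = 4) -> Partition:
    """Partitioning Around Medoids: BUILD + best-swap SWAP passes, restarted.

    Works on points (Euclidean) or a precomputed distance matrix.  Medoids
    are always data points and the objective (total distance to the nearest
    medoid) is non-increasing across swaps.  SWAP descends from the BUILD
    start and from ``n_restarts`` seeded random starts (SWAP alone is a local
    search; extra starts let small instances reach the global optimum); the
    lowest-objective result wins, ties breaking toward the lowest indices, so
    the outcome is deterministic given the seed.
    """
    D, _ = _as_distance(rep)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")

    rng = np.random.default_rng(seed)
    starts = [_pam_build(D, k)]
    for _ in range(n_restarts):
        starts.append(np.sort(rng.choice(n, size=k, replace=False)))

    best_medoids, best_obj = None, np.inf
    for start in starts:
        medoids = _swap_descent(D, start.copy(), k, max_iter)
        obj = pam_objective(D, medoids)
        if obj < best_obj - 1e-12:
            best_obj, best_medoids = obj, medoids
    medoids = best_medoids
    labels = np.argmin(D[:, medoids], axis=1)
    return Partition(labels=labels, method="pam",
                     hyperparams={"k": k, "medoids": medoids.tolist(), "seed": seed})


def _swap_descent(D: np.ndarray, medoids: np.ndarray, k: int,
                  max_iter: int) -> np.ndarray:
    n = D.shape[0]
    for _ in range(max_iter):
        dm = D[:, medoids]
        part = np.argpartition(dm, 1, axis=1)[:, :2] if k > 1 else np.zeros((n, 1), int)
        if k > 1:
            two = np.take_along_axis(dm, part, axis=1)
            swap_order = np.argsort(two, axis=1)
            nearest = part[np.arange(n), swap_order[:, 0]]
            d1 = two[np.arange(n), swap_order[:, 0]]
            d2 = two[np.arange(n), swap_order[:, 1]]
        else:
            nearest = np.zeros(n, dtype=int)
            d1 = dm[:, 0]
            d2 = np.full(n, np.inf)

        best_delta, best_pair = -1e-12, None
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        for h in np.flatnonzero(~is_medoid):
            dh = D[:, h]
            base = np.minimum(d1, dh)
            shared = base - d1                       # change if no owned medoid removed
            corr = np.minimum(d2, dh) - base         # extra cost for points owned by i
            delta = shared.sum() + np.bincount(nearest, weights=corr, minlength=k)
            i = int(np.argmin(delta))
            if delta[i] < best_delta:
                best_delta, best_pair = float(delta[i]), (i, h)
        if best_pair is None:
            break
        i, h = best_pair
        medoids[i] = h
        medoids = np.array(sorted(medoids))
    return medoids


def spectral(rep: np.ndarray | DistanceMatrix, k: int,
             affinity: str = "knn", n_neighbors: int = 15,
             gamma: float = 1.0, seed: int = 0) -> Partition:
    """Normalized-cut spectral clustering with a kNN or RBF affinity.

    On a precomputed distance matrix the RBF affinity is exp(-gamma * d^2)
    and the kNN affinity is a symmetrized k-nearest-neighbor graph.  A
    disconnected affinity graph is flagged with a warning; clustering is
    still returned (components are then split by the solver).
    """
    D, precomputed = _as_distance(rep)
    n = D.shape[0]
    if k == 1:
        return Partition(labels=np.zeros(n, dtype=int), method="spectral",
                         hyperparams={"k": 1, "affinity": affinity, "seed": seed})
    if not 2 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}")
    if affinity == "knn":
        if n_neighbors >= n:
            raise ValueError("n_neighbors must be smaller than n")
        conn = kneighbors_graph(D, n_neighbors=n_neighbors, metric="precomputed")
        A = 0.5 * (conn + conn.T)
        n_comp, _ = connected_components(A, directed=False)
        if n_comp > 1:
            warnings.warn(f"affinity graph has {n_comp} connected components")
        model = SpectralClustering(n_clusters=k, affinity="precomputed",
                                   random_state=seed, assign_labels="kmeans")
        labels = model.fit_predict(A.toarray())
    elif affinity == "rbf":
        A = np.exp(-gamma * D ** 2)
        model = SpectralClustering(n_clusters=k, affinity="precomputed",
                                   random_state=seed, assign_labels="kmeans")
        labels = model.fit_predict(A)
    else:
        raise ValueError(f"unknown affinity {affinity!r}")
    hp = {"k": k, "affinity": affinity, "seed": seed}
    hp["n_neighbors" if affinity == "knn" else "gamma"] = (
        n_neighbors if affinity == "knn" else gamma)
    return Partition(labels=labels, method="spectral", hyperparams=hp)


def hdbscan_cluster(rep: np.ndarray | DistanceMatrix, min_cluster_size: int = 5,
                    min_samples: int = 5) -> Partition:
    """Hierarchical density-based clustering; low-density points become noise."""
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be at least 2")
    if isinstance(rep, DistanceMatrix):
        X, metric = rep.values, "precomputed"
        n = X.shape[0]
    else:
        X = np.asarray(rep, dtype=float)
        metric = "euclidean"
        n = X.shape[0]
    if min_cluster_size > n or min_samples > n:
        raise ValueError("min_cluster_size/min_samples exceed the number of points")
    hp = {"min_cluster_size": min_cluster_size, "min_samples": min_samples}
    if np.ptp(X, axis=0).max(initial=0.0) == 0.0 and metric != "precomputed":
        # all points identical: a single degenerate cluster
        return Partition(labels=np.zeros(n, dtype=int), method="hdbscan", hyperparams=hp)
    model = HDBSCAN(min_cluster_size=min_cluster_size, min_samples=min_samples,
                    metric=metric)
    labels = model.fit_predict(X)
    return Partition(labels=labels, method="hdbscan", hyperparams=hp)


def assign_by_driver_taxa(t: AbundanceTable,
                          drivers: tuple[str, ...] = DRIVER_GENERA) -> Partition:
    """Label each sample by its most abundant driver genus.

    The classical enterotype assignment: argmax relative abundance among the
    driver taxa (ties, including all-zero rows, go to the lowest driver
    index).  Requires a genus-level table containing at least one driver.
    """
    cols = []
    found = []
    for name in drivers:
        if name in t.taxon_ids:
            cols.append(t.taxon_ids.index(name))
            found.append(name)
    if not cols:
        raise ValueError(
            f"none of the driver taxa {drivers} found; available: {t.taxon_ids[:20]}...")
    sub = t.matrix[:, cols]
    labels = np.argmax(sub, axis=1)  # argmax takes the first maximum: lowest index
    n_ties = int((sub == sub.max(axis=1, keepdims=True)).sum(axis=1).max())
    if n_ties > 1:
        warnings.warn("ties in driver-taxon assignment resolved to the lowest index")
    return Partition(labels=labels, method="driver_taxa",
                     hyperparams={"drivers": list(found)})


def sweep_clusterings(representations: dict[str, np.ndarray | DistanceMatrix],
                      grids: dict | None = None, seed: int = 0) -> list[Partition]:
    """Cartesian product of representations × methods × hyperparameter grids.

    Default grids follow the framework's published ranges: k in 2..9 for PAM
    and spectral; neighborhood sizes {5, 15, 25, 50} (kNN affinity) or gamma
    {1, 5, 10, 15} (RBF on precomputed distances); HDBSCAN min_cluster_size
    {5, 10, 25, 50} × min_samples {5, 10, 15, 20}.  Identical label vectors
    within one representation collapse into a single partition with merged
    provenance.
    """
    if not representations:
        raise ValueError("no representations given")
    if grids is None:
        grids = {}
    k_range = grids.get("k_range", range(2, 10))
    neighborhoods = grids.get("spectral_neighbors", (5, 15, 25, 50))
    gammas = grids.get("spectral_gamma", (1, 5, 10, 15))
    mcs_grid = grids.get("hdbscan_min_cluster_size", (5, 10, 25, 50))
    ms_grid = grids.get("hdbscan_min_samples", (5, 10, 15, 20))
    methods = grids.get("methods", ("pam", "spectral", "hdbscan"))

    out: list[Partition] = []
    for rep_id, rep in representations.items():
        seen: dict[bytes, Partition] = {}

        def _add(p: Partition) -> None:
            p.representation_id = rep_id
            prov = dict(representation=rep_id, method=p.method,
                        hyperparams=dict(p.hyperparams))
            key = p.labels.tobytes()
            if key in seen:
                seen[key].provenance.append(prov)
            else:
                p.provenance = [prov]
                seen[key] = p
                out.append(p)

        n = rep.values.shape[0] if isinstance(rep, DistanceMatrix) else np.asarray(rep).shape[0]
        precomputed = isinstance(rep, DistanceMatrix)
        if "pam" in methods:
            for k in k_range:
                _add(pam(rep, k=k, seed=seed))
        if "spectral" in methods:
            for k in k_range:
                if precomputed:
                    for g in gammas:
                        _add(spectral(rep, k=k, affinity="rbf", gamma=g, seed=seed))
                else:
                    for nb in neighborhoods:
                        if nb < n:
                            _add(spectral(rep, k=k, affinity="knn",
                                          n_neighbors=nb, seed=seed))
        if "hdbscan" in methods:
            for mcs in mcs_grid:
                for ms in ms_grid:
                    if mcs <= n and ms <= n:
                        _add(hdbscan_cluster(rep, min_cluster_size=mcs, min_samples=ms))
    return out
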