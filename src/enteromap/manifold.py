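"""Nonlinear dimensionality reduction behind one contract, plus its quality scores.

Six embedding backends (Isomap, LLE, spectral embedding, t-SNE, UMAP and a
small numpy denoising autoencoder) share a uniform signature: input matrix,
target dimension, named hyperparameters, seed.  Every embedding is scored by

* reconstruction MAE — the median, over points, of the L1 error when a
  point's original-space coordinates are predicted by distance-weighted
  k-nearest-neighbor regression from the embedding space, leave-one-out;
* co-ranking quality — Q_NX(K) curves split at the LCMC maximum into a local
  (q_loc) and a global (q_glob) neighborhood-preservation score.

Hyperparameters are swept on a small grid and chosen by lowest MAE; up to 10%
of points with the worst reconstruction error may then be discarded as
denoising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE, Isomap, LocallyLinearEmbedding, SpectralEmbedding
from sklearn.neighbors import LocalOutlierFactor, NearestNeighbors

__all__ = [
    "Embedding",
    "EMBED_METHODS",
    "DEFAULT_GRIDS",
    "embed",
    "loo_knn_reconstruct",
    "coranking_quality",
    "sweep_hyperparams",
    "discard_worst",
    "lof_outliers",
]

EMBED_METHODS = ("isomap", "lle", "spectral", "tsne", "umap", "autoencoder")

#: per-method hyperparameter grids on the scale of 8-40 combinations
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "isomap": [{"n_neighbors": k} for k in (5, 10, 15, 25, 50)],
    "lle": [{"n_neighbors": k} for k in (5, 10, 15, 25, 50)],
    "spectral": [{"n_neighbors": k} for k in (5, 15, 25, 50)],
    "tsne": [{"perplexity": p} for p in (10, 30, 50)],
    "umap": [{"n_neighbors": k, "min_dist": md}
             for k in (5, 15, 25, 50) for md in (0.1, 0.5)],
    "autoencoder": [{"hidden": h} for h in (32, 64)],
}


@dataclass
class Embedding:
    method: str
    hyperparams: dict
    coords: np.ndarray            # (n', d_target)
    kept_indices: np.ndarray      # indices into the source matrix
    mae: float
    q_loc: float
    q_glob: float
    seed: int
    sweep_table: list[dict] = field(default_factory=list)
    converged: bool = True


def _autoencoder_embed(X: np.ndarray, d_target: int, hidden: int = 32,
                       noise_sd: float = 0.05, epochs: int = 300,
                       lr: float = 1e-3, seed: int = 0) -> np.ndarray:
    """Tiny fully-connected denoising autoencoder trained with Adam.

    Architecture d -> hidden -> d_target -> hidden -> d with tanh activations
    on the hidden layers; inputs are corrupted with Gaussian noise during
    training.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n, d = X.shape
    mu, sd = X.mean(0), X.std(0) + 1e-12
    Z = (X - mu) / sd
    sizes = [(d, hidden), (hidden, d_target), (d_target, hidden), (hidden, d)]
    W = [rng.standard_normal(s) * np.sqrt(2.0 / s[0]) for s in sizes]
    b = [np.zeros(s[1]) for s in sizes]
    mW = [np.zeros_like(w) for w in W]; vW = [np.zeros_like(w) for w in W]
    mB = [np.zeros_like(x) for x in b]; vB = [np.zeros_like(x) for x in b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def forward(inp):
        h1 = np.tanh(inp @ W[0] + b[0])
        code = h1 @ W[1] + b[1]
        h2 = np.tanh(code @ W[2] + b[2])
        out = h2 @ W[3] + b[3]
        return h1, code, h2, out

    t = 0
    for _ in range(epochs):
        noisy = Z + noise_sd * rng.standard_normal(Z.shape)
        h1, code, h2, out = forward(noisy)
        g_out = 2.0 * (out - Z) / n
        grads_W, grads_b = [None] * 4, [None] * 4
        grads_W[3] = h2.T @ g_out; grads_b[3] = g_out.sum(0)
        g_h2 = (g_out @ W[3].T) * (1 - h2 ** 2)
        grads_W[2] = code.T @ g_h2; grads_b[2] = g_h2.sum(0)
        g_code = g_h2 @ W[2].T
        grads_W[1] = h1.T @ g_code; grads_b[1] = g_code.sum(0)
        g_h1 = (g_code @ W[1].T) * (1 - h1 ** 2)
        grads_W[0] = noisy.T @ g_h1; grads_b[0] = g_h1.sum(0)
        t += 1
        for i in range(4):
            mW[i] = beta1 * mW[i] + (1 - beta1) * grads_W[i]
            vW[i] = beta2 * vW[i] + (1 - beta2) * grads_W[i] ** 2
            mB[i] = beta1 * mB[i] + (1 - beta1) * grads_b[i]
            vB[i] = beta2 * vB[i] + (1 - beta2) * grads_b[i] ** 2
            corr1, corr2 = 1 - beta1 ** t, 1 - beta2 ** t
            W[i] -= lr * (mW[i] / corr1) / (np.sqrt(vW[i] / corr2) + eps)
            b[i] -= lr * (mB[i] / corr1) / (np.sqrt(vB[i] / corr2) + eps)
    _, code, _, _ = forward(Z)
    return code


def embed(X: np.ndarray, method: str, d_target: int,
          hyperparams: dict | None = None, seed: int = 0) -> np.ndarray:
    """Embed ``X`` to ``d_target`` dimensions with the named backend."""
    X = np.asarray(X, dtype=float)
    hp = dict(hyperparams or {})
    if method not in EMBED_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {EMBED_METHODS}")
    if d_target > X.shape[1]:
        raise ValueError(f"d_target={d_target} exceeds input dimension {X.shape[1]}")

    if method == "isomap":
        # dense eigensolver: ARPACK takes an unseedable random start vector
        model = Isomap(n_components=d_target, n_neighbors=hp.get("n_neighbors", 15),
                       eigen_solver="dense")
        return model.fit_transform(X)
    if method == "lle":
        model = LocallyLinearEmbedding(
            n_components=d_target, n_neighbors=hp.get("n_neighbors", 15),
            reg=hp.get("reg", 1e-3), random_state=seed)
        return model.fit_transform(X)
    if method == "spectral":
        model = SpectralEmbedding(
            n_components=d_target, n_neighbors=hp.get("n_neighbors", 15),
            affinity="nearest_neighbors", random_state=seed)
        return model.fit_transform(X)
    if method == "tsne":
        n = X.shape[0]
        perplexity = min(hp.get("perplexity", 30), (n - 1) / 3.0)
        model = TSNE(n_components=d_target, perplexity=perplexity,
                     method="barnes_hut" if d_target <= 3 else "exact",
                     max_iter=hp.get("max_iter", 500), init="pca",
                     random_state=seed)
        return model.fit_transform(X)
    if method == "umap":
        import umap  # deferred: numba-compiled import is slow

        model = umap.UMAP(n_components=d_target,
                          n_neighbors=hp.get("n_neighbors", 15),
                          min_dist=hp.get("min_dist", 0.1),
                          random_state=seed)
        return np.asarray(model.fit_transform(X), dtype=float)
    return _autoencoder_embed(X, d_target, hidden=hp.get("hidden", 32),
                              noise_sd=hp.get("noise_sd", 0.05),
                              epochs=hp.get("epochs", 300), seed=seed)


def loo_knn_reconstruct(X_orig: np.ndarray, coords: np.ndarray,
                        k: int = 5) -> tuple[np.ndarray, float]:
    """Leave-one-out kNN regression from the embedding back to the data space.

    Each point's original-space coordinates are predicted as the
    inverse-distance-weighted average of the original coordinates of its k
    nearest embedding-space neighbors (self excluded; exact matches take all
    the weight).  Returns per-point L1 residual norms and their median (MAE).
    """
    X_orig = np.asarray(X_orig, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # drop self wherever it appears in the neighbor list (ties permitting)
    self_col = idx == np.arange(n)[:, None]
    keep = np.where(self_col, False, True)
    # ensure exactly k neighbors per row: drop the last kept one if self absent
    for i in np.flatnonzero(keep.sum(1) > k):
        keep[i, np.flatnonzero(keep[i])[-1]] = False
    dist = dist[keep].reshape(n, k)
    idx = idx[keep].reshape(n, k)

    with np.errstate(divide="ignore"):
        w = 1.0 / dist
    exact = dist == 0.0
    has_exact = exact.any(axis=1)
    w[has_exact] = exact[has_exact].astype(float)
    w /= w.sum(axis=1, keepdims=True)
    pred = np.einsum("nk,nkd->nd", w, X_orig[idx])
    per_point = np.abs(X_orig - pred).sum(axis=1)
    return per_point, float(np.median(per_point))


def _rank_matrix(X: np.ndarray) -> np.ndarray:
    """(n, n) matrix of neighbor ranks: entry (i, j) is the rank of j from i."""
    from scipy.spatial.distance import squareform, pdist

    D = squareform(pdist(X))
    order = np.argsort(D, axis=1, kind="stable")
    ranks = np.empty_like(order)
    n = X.shape[0]
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(n)[None, :]
    return ranks  # self has rank 0


def coranking_quality(X_orig: np.ndarray, coords: np.ndarray,
                      k_max: int | None = None) -> tuple[float, float]:
    """Local and global structure preservation from the co-ranking matrix.

    Q_NX(K) is the average fraction of each point's K original-space
    neighbors that stay within its K embedding-space neighbors.  The curve is
    split at the K maximizing LCMC(K) = Q_NX(K) - K/(n-1): q_loc averages
    Q_NX below the split, q_glob above it (up to ``k_max``).
    """
    X_orig = np.asarray(X_orig, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = X_orig.shape[0]
    if n < 10:
        raise ValueError("need at least 10 points")
    if k_max is None:
        k_max = n - 1
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be smaller than n={n}")
    r_orig = _rank_matrix(X_orig)
    r_emb = _rank_matrix(coords)
    mask = ~np.eye(n, dtype=bool)
    a = r_orig[mask]  # ranks 1..n-1
    b = r_emb[mask]
    # co-ranking matrix as a 2-D histogram over rank pairs
    Q = np.zeros((n - 1, n - 1), dtype=np.int64)
    np.add.at(Q, (a - 1, b - 1), 1)
    cum = Q.cumsum(axis=0).cumsum(axis=1)
    K = np.arange(1, k_max + 1)
    q_nx = cum[K - 1, K - 1] / (K * n)
    lcmc = q_nx - K / (n - 1)
    k_star = int(K[np.argmax(lcmc)])
    q_loc = float(np.mean(q_nx[:k_star]))
    q_glob = float(np.mean(q_nx[k_star:])) if k_star < k_max else float(q_nx[-1])
    return q_loc, q_glob


def qnx_curve(X_orig: np.ndarray, coords: np.ndarray, k_max: int) -> np.ndarray:
    """The raw Q_NX(K) curve for K = 1..k_max (shared with the tests)."""
    n = X_orig.shape[0]
    r_orig = _rank_matrix(np.asarray(X_orig, float))
    r_emb = _rank_matrix(np.asarray(coords, float))
    mask = ~np.eye(n, dtype=bool)
    Q = np.zeros((n - 1, n - 1), dtype=np.int64)
    np.add.at(Q, (r_orig[mask] - 1, r_emb[mask] - 1), 1)
    cum = Q.cumsum(axis=0).cumsum(axis=1)
    K = np.arange(1, k_max + 1)
    return cum[K - 1, K - 1] / (K * n)


def sweep_hyperparams(X: np.ndarray, method: str, grid: list[dict] | None,
                      d_target: int, seed: int = 0, k_reconstruct: int = 5,
                      X_score: np.ndarray | None = None) -> Embedding:
    """Fit every grid combination and keep the lowest-reconstruction-MAE one.

    ``X_score`` (default ``X``) is the space reconstruction error and
    co-ranking quality are measured against — pass the original abundances
    when embedding PCA scores.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[method]
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if len(grid) > 40:
        raise ValueError("grid larger than 40 combinations")
    X = np.asarray(X, dtype=float)
    target = X if X_score is None else np.asarray(X_score, dtype=float)
    best = None
    table = []
    for hp in grid:
        coords = embed(X, method, d_target, hp, seed=seed)
        _, mae = loo_knn_reconstruct(target, coords, k=k_reconstruct)
        table.append(dict(method=method, hyperparams=dict(hp), mae=mae))
        if best is None or mae < best[1]:
            best = (coords, mae, dict(hp))
    coords, mae, hp = best
    q_loc, q_glob = coranking_quality(target, coords)
    return Embedding(method=method, hyperparams=hp, coords=coords,
                     kept_indices=np.arange(X.shape[0]), mae=mae,
                     q_loc=q_loc, q_glob=q_glob, seed=seed, sweep_table=table)


def discard_worst(X: np.ndarray, e: Embedding, max_fraction: float = 0.10,
                  step: float = 0.02, k_reconstruct: int = 5,
                  rel_improvement: float = 0.01) -> Embedding:
    """Denoise by iteratively dropping the points hardest to reconstruct.

    Repeats {recompute leave-one-out errors on the kept set, drop the worst
    ``step`` fraction of the original n} until ``max_fraction`` is removed or
    the MAE improvement falls below ``rel_improvement`` relative.  Quality
    scores are recomputed on the kept points.
    """
    if not 0.0 < max_fraction <= 0.10:
        raise ValueError("max_fraction must lie in (0, 0.10]")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    kept = np.array(e.kept_indices, dtype=int)
    coords = e.coords
    per_point, mae = loo_knn_reconstruct(X[kept], coords, k=k_reconstruct)
    n_step = max(int(round(step * n)), 1)
    while n - kept.size + n_step <= int(round(max_fraction * n)):
        worst = np.argsort(per_point, kind="stable")[-n_step:]
        keep_mask = np.ones(kept.size, dtype=bool)
        keep_mask[worst] = False
        new_kept, new_coords = kept[keep_mask], coords[keep_mask]
        new_pp, new_mae = loo_knn_reconstruct(X[new_kept], new_coords, k=k_reconstruct)
        if mae > 0 and (mae - new_mae) / mae < rel_improvement:
            break
        kept, coords, per_point, mae = new_kept, new_coords, new_pp, new_mae
    q_loc, q_glob = coranking_quality(X[kept], coords)
    return Embedding(method=e.method, hyperparams=e.hyperparams, coords=coords,
                     kept_indices=kept, mae=mae, q_loc=q_loc, q_glob=q_glob,
                     seed=e.seed, sweep_table=e.sweep_table, converged=e.converged)


def lof_outliers(coords: np.ndarray, n_neighbors: int = 20,
                 threshold: float = 1.5) -> np.ndarray:
    """Boolean mask of Local Outlier Factor outliers (LOF score > threshold)."""
    coords = np.asarray(coords, dtype=float)
    if n_neighbors >= coords.shape[0]:
        raise ValueError("n_neighbors must be smaller than the number of points")
    lof = LocalOutlierFactor(n_neighbors=n_neighbors)
    lof.fit(coords)
    return -lof.negative_outlier_factor_ > threshold
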