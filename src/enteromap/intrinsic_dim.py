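"""Levina–Bickel maximum-likelihood intrinsic dimension with a k-sweep and bootstrap.

For a point x and neighborhood cardinality k the local MLE of the dimension is

    m_k(x) = [ (1/(k-1)) * sum_{j=1}^{k-1} ln( T_k(x) / T_j(x) ) ]^(-1),

with T_j(x) the Euclidean distance from x to its j-th nearest neighbor.
Estimates are pooled over points by arithmetic mean at each k, the median is
taken over the neighborhood sweep, and the whole procedure is bootstrapped;
the reported integer dimension is the rounded median of the bootstrap draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["IntrinsicDimEstimate", "estimate_intrinsic_dim", "levina_bickel_per_k"]


@dataclass
class IntrinsicDimEstimate:
    per_k: dict[int, float]          # pooled estimate on the full data, per k
    bootstrap_draws: np.ndarray      # median-over-k estimate per bootstrap trial
    d_mle: int
    k_range: tuple[int, int]
    n_boot: int
    seed: int


def _dedupe_jitter(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Perturb exact duplicate rows by tiny jitter so log-ratios stay finite."""
    _, inverse, counts = np.unique(X, axis=0, return_inverse=True, return_counts=True)
    dup = counts[inverse] > 1
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate points jittered before kNN")
        scale = 1e-12 * max(np.abs(X).max(), 1.0)
        X = X.copy()
        X[dup] += scale * rng.standard_normal((int(dup.sum()), X.shape[1]))
    return X


def levina_bickel_per_k(X: np.ndarray, k_min: int, k_max: int,
                        pooling: str = "mean") -> np.ndarray:
    """Pooled Levina–Bickel estimate for every k in [k_min, k_max].

    ``pooling='mean'`` is the original arithmetic mean of local estimates;
    ``pooling='inverse-mean'`` applies the MacKay–Ghahramani correction
    (average the inverse estimates, then invert).
    """
    n = X.shape[0]
    if k_max > n - 2:
        raise ValueError(f"k_max={k_max} needs more than {k_max + 2} points, got n={n}")
    nn = NearestNeighbors(n_neighbors=k_max + 1).fit(X)
    dist, _ = nn.kneighbors(X)  # includes self at column 0 distance 0
    T = dist[:, 1:]             # (n, k_max) distances to 1..k_max-th neighbors
    if not np.isfinite(T).all():
        raise ValueError("non-finite neighbor distances")
    if (T <= 0).any():
        raise ValueError("zero neighbor distance; dedupe/jitter the input first")
    logT = np.log(T)
    cum = np.cumsum(logT, axis=1)
    out = np.empty(k_max - k_min + 1)
    for i, k in enumerate(range(k_min, k_max + 1)):
        # sum_{j<k} ln(T_k/T_j) = (k-1) ln T_k - sum_{j<k} ln T_j
        s = (k - 1) * logT[:, k - 1] - cum[:, k - 2]
        inv_m = s / (k - 1)          # 1 / m_k(x)
        if pooling == "mean":
            out[i] = np.mean(1.0 / inv_m)
        elif pooling == "inverse-mean":
            out[i] = 1.0 / np.mean(inv_m)
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
    return out


def estimate_intrinsic_dim(X: np.ndarray, k_range: tuple[int, int] = (5, 100),
                           n_boot: int = 50, seed: int = 0,
                           pooling: str = "mean") -> IntrinsicDimEstimate:
    """Bootstrap the pooled k-sweep and report the rounded median draw.

    Each bootstrap trial resamples points with replacement; duplicate rows
    within a trial are dropped before the neighbor query (the resampled
    geometry, not the multiplicities, carries the dimension information).
    """
    X = np.asarray(X, dtype=float)
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if k_min < 2 or k_min > k_max:
        raise ValueError("k_range must satisfy 2 <= k_min <= k_max")
    n = X.shape[0]
    if n <= k_max + 1:
        raise ValueError(f"need n > max(k_range)+1 = {k_max + 1}, got n={n}")
    rng = np.random.default_rng(seed)
    X = _dedupe_jitter(X, rng)

    per_k_vals = levina_bickel_per_k(X, k_min, k_max, pooling=pooling)
    per_k = {k: float(v) for k, v in zip(range(k_min, k_max + 1), per_k_vals)}

    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.unique(rng.integers(0, n, size=n))
        Xb = X[idx]
        kb_max = min(k_max, Xb.shape[0] - 2)
        draws[b] = float(np.median(levina_bickel_per_k(Xb, k_min, kb_max, pooling=pooling)))

    med = float(np.median(draws))
    d_mle = int(np.floor(med + 0.5))  # round half-up to integer
    return IntrinsicDimEstimate(per_k=per_k, bootstrap_draws=draws,
                                d_mle=max(d_mle, 1), k_range=(k_min, k_max),
                                n_boot=n_boot, seed=seed)
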