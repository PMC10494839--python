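"""2-D/3-D visualization embeddings, KDE density, high-density regions, top taxa.

Even without discrete clusters, compositional data can concentrate along a
manifold with regions of preferential density.  This module quantifies that:
a seeded t-SNE/UMAP projection, Gaussian KDE whose bandwidth is the median
distance from every point to its 100 nearest neighbors, the 70th-percentile
high-density point set split into connected regions, and per-region
summaries of the most abundant taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import KernelDensity, NearestNeighbors, radius_neighbors_graph

from .manifold import embed, lof_outliers
from .preprocess import AbundanceTable

__all__ = ["DensityMap", "project_viz", "kde_density",
           "high_density_regions", "top_taxa_per_region"]


@dataclass
class DensityMap:
    coords: np.ndarray                 # (n, 2 or 3)
    density: np.ndarray | None = None  # relative likelihood at the points
    bandwidth: float | None = None
    threshold: float | None = None
    region_labels: np.ndarray | None = None  # -1 below threshold
    kept_indices: np.ndarray | None = None   # indices into the source table


def project_viz(X: np.ndarray, method: str = "umap", dims: int = 2,
                seed: int = 0, hyperparams: dict | None = None,
                lof_fraction: float = 0.01) -> DensityMap:
    """Seeded 2-D/3-D t-SNE or UMAP projection with small-cluster removal.

    After projecting, points flagged by the Local Outlier Factor are removed
    when they amount to less than ``lof_fraction`` of the data (stray
    slivers torn off the manifold by the projection, not structure).
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if method not in ("tsne", "umap"):
        raise ValueError("visualization method must be 'tsne' or 'umap'")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 points")
    if X.shape[1] < dims:  # already lower-dimensional than the target
        X = np.pad(X, ((0, 0), (0, dims - X.shape[1])))
    coords = embed(X, method, dims, hyperparams, seed=seed)
    kept = np.arange(X.shape[0])
    if 0 < lof_fraction < 1 and X.shape[0] > 25:
        mask = lof_outliers(coords, n_neighbors=min(20, X.shape[0] - 1))
        if 0 < mask.sum() <= lof_fraction * X.shape[0]:
            kept = np.flatnonzero(~mask)
            coords = coords[~mask]
    return DensityMap(coords=coords, kept_indices=kept)


def kde_density(dm: DensityMap | np.ndarray, n_bw_neighbors: int = 100) -> DensityMap:
    """Gaussian KDE evaluated at the data points.

    The bandwidth is the median of the pooled distances from every point to
    its ``n_bw_neighbors`` nearest neighbors — a scale set by the data's own
    local spacing rather than by a plug-in rule.
    """
    coords = dm.coords if isinstance(dm, DensityMap) else np.asarray(dm, dtype=float)
    n = coords.shape[0]
    if n <= n_bw_neighbors:
        raise ValueError(f"need more than {n_bw_neighbors} points, got {n}")
    nn = NearestNeighbors(n_neighbors=n_bw_neighbors + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    bandwidth = float(np.median(dist[:, 1:]))
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth).fit(coords)
    density = np.exp(kde.score_samples(coords))
    kept = dm.kept_indices if isinstance(dm, DensityMap) else None
    return DensityMap(coords=coords, density=density, bandwidth=bandwidth,
                      kept_indices=kept)


def high_density_regions(dm: DensityMap, percentile: float = 0.70,
                         min_region_fraction: float = 0.01) -> DensityMap:
    """Keep points at or above the density percentile; label connected regions.

    Supra-threshold points are grouped by single-linkage connectivity at the
    KDE bandwidth: two points belong to the same region when a chain of
    supra-threshold points with consecutive gaps <= bandwidth joins them.
    Regions holding less than ``min_region_fraction`` of all points merge
    into the noise label -1, as do all sub-threshold points.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    if dm.density is None or dm.bandwidth is None:
        raise ValueError("run kde_density first")
    n = dm.coords.shape[0]
    threshold = float(np.quantile(dm.density, percentile))
    high = dm.density >= threshold
    region_labels = np.full(n, -1, dtype=int)
    pts = dm.coords[high]
    if pts.shape[0]:
        if pts.shape[0] == 1:
            comp = np.zeros(1, dtype=int)
        else:
            graph = radius_neighbors_graph(pts, radius=dm.bandwidth,
                                           mode="connectivity")
            _, comp = connected_components(graph, directed=False)
        labels = np.full(pts.shape[0], -1, dtype=int)
        next_id = 0
        for c in np.unique(comp):
            mask = comp == c
            if mask.sum() >= min_region_fraction * n:
                labels[mask] = next_id
                next_id += 1
        region_labels[high] = labels
    return DensityMap(coords=dm.coords, density=dm.density,
                      bandwidth=dm.bandwidth, threshold=threshold,
                      region_labels=region_labels, kept_indices=dm.kept_indices)


def top_taxa_per_region(t: AbundanceTable, dm: DensityMap,
                        n_top: int = 10) -> pd.DataFrame:
    """Distribution summaries of the dominant taxa inside each density region.

    The ``n_top`` taxa are ranked by mean abundance pooled over *all*
    supra-threshold points; the table reports, per (region, taxon), the mean
    and quartiles of that taxon's relative abundance within the region.
    """
    if dm.region_labels is None:
        raise ValueError("run high_density_regions first")
    idx = dm.kept_indices if dm.kept_indices is not None else np.arange(t.n)
    if len(idx) != dm.coords.shape[0]:
        raise ValueError("density map and table are not aligned")
    M = t.matrix[idx]
    high = dm.region_labels >= 0
    if not high.any():
        raise ValueError("no supra-threshold points")
    pooled_mean = M[high].mean(axis=0)
    if n_top > t.d:
        n_top = t.d
    top = np.argsort(-pooled_mean, kind="stable")[:n_top]
    rows = []
    for region in np.unique(dm.region_labels[high]):
        mask = dm.region_labels == region
        for j in top:
            vals = M[mask, j]
            rows.append({
                "region": int(region),
                "taxon_id": t.taxon_ids[j],
                "mean": float(vals.mean()),
                "q25": float(np.quantile(vals, 0.25)),
                "median": float(np.quantile(vals, 0.5)),
                "q75": float(np.quantile(vals, 0.75)),
                "n_points": int(mask.sum()),
            })
    return pd.DataFrame(rows)
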