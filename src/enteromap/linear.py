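"""Linear reduction: PCA to the 99%-variance subspace, loadings, inversion.

PCA runs on centered but otherwise unscaled relative abundances, and scores
keep their variances (no whitening): rescaling the retained axes would
distort the geometry the later clustering stages depend on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .preprocess import AbundanceTable

__all__ = ["PCAModel", "fit_pca", "pca_loadings", "inverse_pca"]


@dataclass
class PCAModel:
    mean: np.ndarray                      # (d,)
    components: np.ndarray                # (d_pca, d), orthonormal rows
    eigenvalues: np.ndarray               # (d_pca,) variances along components
    explained_variance_ratio: np.ndarray  # (d_pca,)
    d_pca: int


def fit_pca(t: AbundanceTable | np.ndarray,
            variance_threshold: float = 0.99) -> tuple[PCAModel, np.ndarray]:
    """Fit PCA and keep the smallest leading subspace reaching the threshold.

    Returns the model and the (n, d_pca) mean-centered scores.  ``d_pca`` is
    the smallest number of leading components whose cumulative explained
    variance ratio is at least ``variance_threshold``.
    """
    X = t.matrix if isinstance(t, AbundanceTable) else np.asarray(t, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must lie in (0, 1]")
    full = PCA(svd_solver="full").fit(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    d_pca = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    d_pca = min(d_pca, len(cum))
    model = PCAModel(
        mean=full.mean_,
        components=full.components_[:d_pca],
        eigenvalues=full.explained_variance_[:d_pca],
        explained_variance_ratio=full.explained_variance_ratio_[:d_pca],
        d_pca=d_pca,
    )
    scores = (X - full.mean_) @ model.components.T
    return model, scores


def pca_loadings(m: PCAModel) -> np.ndarray:
    """Per-taxon contribution to the retained subspace.

    loading_j = || ( components[i, j] * sqrt(eigenvalue_i) )_i ||_2 over the
    retained components — the Euclidean norm of the eigenvalue-scaled
    principal-vector coordinates of taxon j.
    """
    scaled = m.components * np.sqrt(m.eigenvalues)[:, None]
    return np.sqrt((scaled ** 2).sum(axis=0))


def inverse_pca(m: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Linear reconstruction: mean + scores @ components."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != m.d_pca:
        raise ValueError(f"scores must have {m.d_pca} columns")
    return m.mean + scores @ m.components
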