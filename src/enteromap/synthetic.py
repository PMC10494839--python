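"""Synthetic compositional microbiome-like datasets with known structure.

Real 16S relative-abundance tables (stool surveys of thousands of samples,
hundreds of taxa) are large downloads; the generators here emulate their
geometry — points on the probability simplex, strong sparsity, a dominant
two-taxon trade-off, data concentrated near a low-dimensional nonlinear
submanifold — while recording the ground truth (cluster labels, latent
coordinates, intrinsic dimension) that the downstream stages try to recover.

All generators draw from a single ``numpy.random.Generator`` seeded per call,
so identical arguments reproduce the matrix bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticDataset",
    "generate_clustered",
    "generate_manifold",
    "generate_gradient",
    "add_zero_inflation",
    "write_dataset",
    "read_ground_truth",
]


@dataclass
class SyntheticDataset:
    """A simplex-valued dataset plus the ground truth that generated it.

    Attributes
    ----------
    abundances : (n, p) ndarray
        Relative abundances; every row is nonnegative and sums to 1.
    labels : (n,) int ndarray or None
        Planted cluster ids, when the generator plants clusters.
    latent : (n, d_true) ndarray or None
        Latent manifold coordinates, when the generator uses them.
    d_true : int
        Intrinsic dimension of the generating process.
    params : dict
        All generator arguments, including the seed.
    """

    abundances: np.ndarray
    labels: np.ndarray | None
    latent: np.ndarray | None
    d_true: int
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.abundances.shape[0]

    @property
    def p(self) -> int:
        return self.abundances.shape[1]

    def taxon_names(self) -> list[str]:
        return [f"taxon_{j:03d}" for j in range(self.p)]

    def sample_names(self) -> list[str]:
        return [f"S{i:05d}" for i in range(self.n)]


def _close(rows: np.ndarray) -> np.ndarray:
    """Project nonnegative rows onto the simplex by total-sum scaling."""
    s = rows.sum(axis=1, keepdims=True)
    return rows / s


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def generate_clustered(
    n: int = 1500,
    p: int = 50,
    k: int = 3,
    separation: float = 5.0,
    spread: float = 1.0,
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Logistic-normal mixture on the simplex with ``k`` planted clusters.

    Cluster centers are isotropic Gaussian draws in logit space scaled by
    ``separation``; each sample perturbs its center by ``spread``-scaled
    Gaussian noise and is closed to the simplex by softmax.  ``d_true``
    follows the k-components-span-a-(k-1)-flat convention.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > n:
        raise ValueError(f"cannot plant k={k} clusters in n={n} samples")
    if separation < 0 or spread <= 0:
        raise ValueError("separation must be >= 0 and spread > 0")
    if weights is None:
        weights = np.full(k, 1.0 / k)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (k,) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be a k-vector summing to 1 within 1e-9")

    rng = np.random.default_rng(seed)
    centers = separation * rng.standard_normal((k, p))
    # largest-remainder allocation keeps cluster sizes deterministic
    counts = np.floor(weights * n).astype(int)
    for i in np.argsort(-(weights * n - counts))[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(k), counts)
    logits = centers[labels] + spread * rng.standard_normal((n, p))
    abundances = _softmax(logits)
    params = dict(kind="clustered", n=n, p=p, k=k, separation=separation,
                  spread=spread, weights=weights.tolist(), seed=seed)
    return SyntheticDataset(abundances, labels, None, max(k - 1, 1), params)


def generate_manifold(
    n: int = 2000,
    p: int = 100,
    d_true: int = 2,
    curvature: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Samples concentrated near a ``d_true``-dimensional nonlinear submanifold.

    Latent coordinates are uniform on the unit cube and pushed to ``p``
    logits through a fixed random sinusoidal feature map (random Fourier
    features with frequencies scaled by ``curvature``), so the composition
    inherits the latent manifold exactly; ``noise_sd`` adds Gaussian logit
    noise off the manifold.  No clusters are planted.
    """
    if not 1 <= d_true < p:
        raise ValueError("require 1 <= d_true < p")
    if n < 10:
        raise ValueError("n must be at least 10")
    if curvature < 0 or noise_sd < 0:
        raise ValueError("curvature and noise_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    latent = rng.uniform(size=(n, d_true))
    # one sinusoid per output coordinate; wavelength ~ curvature^-1 cube widths
    freq = 2.0 * np.pi * curvature * rng.standard_normal((d_true, p))
    phase = rng.uniform(0.0, 2.0 * np.pi, size=p)
    amp = rng.uniform(0.5, 2.0, size=p)
    logits = amp * np.sin(latent @ freq + phase)
    if noise_sd > 0:
        logits = logits + noise_sd * rng.standard_normal((n, p))
    abundances = _softmax(logits)
    params = dict(kind="manifold", n=n, p=p, d_true=d_true,
                  curvature=curvature, noise_sd=noise_sd, seed=seed)
    return SyntheticDataset(abundances, None, latent, d_true, params)


def generate_gradient(
    n: int = 1000,
    p: int = 50,
    seed: int = 0,
    dominant_share: float = 0.75,
    background_sd: float = 0.3,
) -> SyntheticDataset:
    """A one-dimensional two-taxon trade-off, the Bacteroides/Prevotella motif.

    A single latent coordinate t ~ U[0,1] moves mass smoothly from taxon 0
    (share ``dominant_share`` at t=0) to taxon 1 (same share at t=1); the
    remaining mass is spread over background taxa by a mildly noisy softmax.
    The result is a continuum — non-uniform in density once embedded, but
    with no density gap anywhere along it.
    """
    if p < 3:
        raise ValueError("p must be at least 3 (two dominant taxa + background)")
    if not 0 < dominant_share < 0.8 + 1e-9:
        raise ValueError("dominant_share must lie in (0, 0.8]")

    rng = np.random.default_rng(seed)
    t = rng.uniform(size=n)
    share0 = dominant_share * (1.0 - t)
    share1 = dominant_share * t
    bg_logits = background_sd * rng.standard_normal((n, p - 2))
    bg = _softmax(bg_logits) * (1.0 - share0 - share1)[:, None]
    abundances = np.column_stack([share0, share1, bg])
    abundances = _close(abundances)
    params = dict(kind="gradient", n=n, p=p, seed=seed,
                  dominant_share=dominant_share, background_sd=background_sd)
    return SyntheticDataset(abundances, None, t[:, None], 1, params)


def add_zero_inflation(ds: SyntheticDataset, dropout: float, seed: int = 0) -> SyntheticDataset:
    """Sparsify a dataset: zero each entry independently with prob ``dropout``.

    Rows are re-closed to sum 1 afterwards; rows that lose all mass are
    re-drawn (guaranteed to terminate for dropout < 1).
    """
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    if dropout == 0.0:
        return ds
    rng = np.random.default_rng(seed)
    keep = rng.random(ds.abundances.shape) >= dropout
    out = ds.abundances * keep
    dead = out.sum(axis=1) == 0
    while dead.any():
        keep = rng.random((int(dead.sum()), ds.p)) >= dropout
        out[dead] = ds.abundances[dead] * keep
        dead = out.sum(axis=1) == 0
    out = _close(out)
    params = dict(ds.params, dropout=dropout, dropout_seed=seed)
    return SyntheticDataset(out, ds.labels, ds.latent, ds.d_true, params)


def write_dataset(ds: SyntheticDataset, table_path: str | Path,
                  truth_path: str | Path | None = None) -> None:
    """Write the abundance TSV (samples in rows) plus a ground-truth JSON sidecar."""
    table_path = Path(table_path)
    df = pd.DataFrame(ds.abundances, index=ds.sample_names(), columns=ds.taxon_names())
    df.index.name = "sample_id"
    df.to_csv(table_path, sep="\t")
    if truth_path is None:
        truth_path = table_path.with_suffix(".truth.json")
    truth = {
        "d_true": int(ds.d_true),
        "labels": None if ds.labels is None else [int(x) for x in ds.labels],
        "latent": None if ds.latent is None else np.asarray(ds.latent).tolist(),
        "params": ds.params,
    }
    Path(truth_path).write_text(json.dumps(truth))


def read_ground_truth(truth_path: str | Path) -> dict:
    truth = json.loads(Path(truth_path).read_text())
    if truth["labels"] is not None:
        truth["labels"] = np.asarray(truth["labels"], dtype=int)
    if truth["latent"] is not None:
        truth["latent"] = np.asarray(truth["latent"], dtype=float)
    return truth
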