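"""Embedding contract, reconstruction MAE, co-ranking quality, denoising."""

import numpy as np
import pytest

from enteromap import (coranking_quality, discard_worst, embed, fit_pca,
                       generate_manifold, lof_outliers, loo_knn_reconstruct,
                       sweep_hyperparams)
from enteromap.manifold import DEFAULT_GRIDS, qnx_curve


@pytest.fixture(scope="module")
def rotated_plane():
    rng = np.random.default_rng(7)
    P = rng.uniform(size=(300, 2))
    X = np.c_[P, np.zeros((300, 8))]
    Q = np.linalg.qr(rng.normal(size=(10, 10)))[0]
    return X @ Q, P


class TestEmbedContract:
    def test_isomap_on_flat_plane_preserves_global_structure(self, rotated_plane):
        X, _ = rotated_plane
        coords = embed(X, "isomap", 2, {"n_neighbors": 50}, seed=0)
        q_loc, q_glob = coranking_quality(X, coords)
        assert q_glob >= 0.99

    def test_target_dimension_validated(self, rng):
        with pytest.raises(ValueError):
            embed(rng.normal(size=(50, 3)), "isomap", 5)
        with pytest.raises(ValueError):
            embed(rng.normal(size=(50, 3)), "nonsense", 2)

    @pytest.mark.parametrize("method", ["lle", "spectral", "tsne", "umap",
                                        "autoencoder"])
    def test_same_seed_reproduces_coordinates(self, method, rng):
        X = rng.normal(size=(80, 6))
        hp = {"epochs": 30} if method == "autoencoder" else {"n_neighbors": 10}
        a = embed(X, method, 2, hp, seed=5)
        b = embed(X, method, 2, hp, seed=5)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (80, 2)


class TestLooReconstruction:
    def test_identity_embedding_of_line_is_exact(self):
        x = np.arange(20.0)[:, None]
        per_point, mae = loo_knn_reconstruct(x, x, k=2)
        assert mae == pytest.approx(0.0, abs=1e-12)
        assert per_point[1:-1].max() == pytest.approx(0.0, abs=1e-12)

    def test_constant_target_is_trivially_reconstructed(self, rng):
        coords = rng.normal(size=(30, 2))
        X = np.ones((30, 5)) * 0.2
        _, mae = loo_knn_reconstruct(X, coords, k=5)
        assert mae == pytest.approx(0.0, abs=1e-12)

    def test_collapsed_embedding_has_positive_error(self, rng):
        X = rng.normal(size=(40, 3))
        coords = np.zeros((40, 2))
        per_point, mae = loo_knn_reconstruct(X, coords, k=5)
        assert mae > 0
        with pytest.raises(ValueError):
            loo_knn_reconstruct(X, coords, k=40)


class TestCoranking:
    def test_identity_embedding_scores_one(self, rng):
        X = rng.normal(size=(100, 3))
        assert coranking_quality(X, X.copy()) == (1.0, 1.0)

    def test_positive_affine_rescaling_is_invisible(self, rng):
        # rank-based scores cannot see a similarity transform of the embedding
        X = rng.normal(size=(60, 4))
        e = X[:, :1]
        a = coranking_quality(X, e)
        b = coranking_quality(X, 3.5 * e + 2.0)
        assert a == b

    def test_random_permutation_matches_chance_level(self, rng):
        """Q_NX(K) of a permuted embedding sits at its chance level K/(n-1)."""
        n = 500
        X = rng.normal(size=(n, 5))
        draws = np.array([
            qnx_curve(X, X[np.random.default_rng(i).permutation(n)], 100)
            for i in range(20)])
        for K in (10, 50, 100):
            vals = draws[:, K - 1]
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - K / (n - 1)) <= 3 * sem
        q_loc, q_glob = coranking_quality(
            X, X[np.random.default_rng(0).permutation(n)], k_max=100)
        assert q_loc < 0.2 and q_glob < 0.2


class TestSweepAndDiscard:
    def test_grid_of_one_and_table_bookkeeping(self, rotated_plane):
        X, _ = rotated_plane
        e = sweep_hyperparams(X, "isomap", [{"n_neighbors": 20}], 2, seed=0)
        assert len(e.sweep_table) == 1
        assert e.hyperparams == {"n_neighbors": 20}
        with pytest.raises(ValueError):
            sweep_hyperparams(X, "isomap", [], 2)

    def test_all_default_grids_are_within_budget(self):
        for method, grid in DEFAULT_GRIDS.items():
            assert 1 <= len(grid) <= 40

    def test_planted_outliers_are_discarded(self, rng):
        ds = generate_manifold(n=500, p=30, d_true=2, curvature=0.8,
                               noise_sd=0.0, seed=2)
        X = ds.abundances.copy()
        out_idx = rng.choice(500, 25, replace=False)
        X[out_idx] = np.random.default_rng(9).dirichlet(np.ones(30) * 0.2, 25)
        _, scores = fit_pca(X)
        e = sweep_hyperparams(scores, "isomap", [{"n_neighbors": 15}], 2,
                              seed=0, X_score=X)
        e2 = discard_worst(X, e, max_fraction=0.10, step=0.02)
        discarded = set(range(500)) - set(e2.kept_indices)
        assert len(e2.kept_indices) >= 0.9 * 500
        assert len(discarded & set(out_idx)) >= 0.8 * 25
        assert e2.mae <= e.mae  # discard never worsens the median error

    def test_discard_fraction_bound_enforced(self, rotated_plane):
        X, _ = rotated_plane
        e = sweep_hyperparams(X, "isomap", [{"n_neighbors": 20}], 2, seed=0)
        with pytest.raises(ValueError):
            discard_worst(X, e, max_fraction=0.5)


class TestLof:
    def test_gross_outlier_flagged_and_null_rate(self, rng):
        blob = rng.normal(0, 1, (100, 2))
        X = np.vstack([blob, [[200.0, 200.0]]])
        mask = lof_outliers(X, n_neighbors=20)
        assert mask.shape == (101,)
        assert mask[-1]
        rates = [lof_outliers(np.random.default_rng(s).uniform(size=(200, 2)),
                              n_neighbors=20).mean() for s in range(10)]
        assert np.mean(rates) < 0.05
        with pytest.raises(ValueError):
            lof_outliers(blob, n_neighbors=200)


def test_finer_taxonomy_is_harder_to_reconstruct():
    """A finer taxon table (more columns) yields higher embedding MAE than the
    same data aggregated to coarser groups — more mass coordinates to place."""
    ds = generate_manifold(n=600, p=120, d_true=2, curvature=1.0,
                           noise_sd=0.1, seed=4)
    fine = ds.abundances
    coarse = fine.reshape(600, 30, 4).sum(axis=2)
    maes = {}
    for name, M in (("fine", fine), ("coarse", coarse)):
        _, scores = fit_pca(M)
        e = sweep_hyperparams(scores, "isomap", [{"n_neighbors": 15}], 2,
                              seed=0, X_score=M)
        maes[name] = e.mae
    assert maes["fine"] > maes["coarse"]
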