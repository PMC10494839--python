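"""Validity metrics: DBCV vs a brute-force oracle, prediction strength,
convex indices, entropy, the threshold gate and partition selection."""

import math

import numpy as np
import pytest

from enteromap import (Partition, convex_metrics, dbcv, gate, pam,
                       partition_entropy, prediction_strength, select_best)
from enteromap.validity import PartitionMetrics


# ---------------------------------------------------------------------------
# Brute-force DBCV oracle: direct formula evaluation with explicit loops and
# Prim's MST, sharing only the definitions (not the code) with the package.

def _oracle_dbcv(X, labels):
    n, m = X.shape
    D = [[math.dist(X[i], X[j]) for j in range(n)] for i in range(n)]
    clusters = sorted(set(l for l in labels if l >= 0))

    def core(members):
        out = []
        for i in members:
            s = 0.0
            for j in members:
                if j != i:
                    s += (1.0 / D[i][j]) ** m
            out.append((s / (len(members) - 1)) ** (-1.0 / m))
        return out

    def prim_mst(nodes, w):
        in_tree = {nodes[0]}
        edges = []
        while len(in_tree) < len(nodes):
            best = None
            for a in sorted(in_tree):
                for b in nodes:
                    if b not in in_tree:
                        if best is None or w[(a, b)] < best[0]:
                            best = (w[(a, b)], a, b)
            edges.append(best)
            in_tree.add(best[2])
        return edges

    info = {}
    for c in clusters:
        members = [i for i in range(n) if labels[i] == c]
        if len(members) < 2:
            info[c] = (0.0, members, {i: 0.0 for i in members})
            continue
        a = dict(zip(members, core(members)))
        w = {}
        for i in members:
            for j in members:
                if i != j:
                    w[(i, j)] = max(a[i], a[j], D[i][j])
        edges = prim_mst(members, w)
        deg = {i: 0 for i in members}
        for _, u, v in edges:
            deg[u] += 1
            deg[v] += 1
        internal = [i for i in members if deg[i] >= 2] or list(members)
        internal_edges = [wt for wt, u, v in edges
                          if u in internal and v in internal]
        sparseness = max(internal_edges) if internal_edges \
            else max(wt for wt, _, _ in edges)
        info[c] = (sparseness, internal, a)

    total = 0.0
    for c in clusters:
        members = [i for i in range(n) if labels[i] == c]
        sparse_c, int_c, a_c = info[c]
        if len(clusters) == 1:
            validity = 0.0
        else:
            min_sep = math.inf
            for o in clusters:
                if o == c:
                    continue
                _, int_o, a_o = info[o]
                for i in int_c:
                    for j in int_o:
                        min_sep = min(min_sep, max(a_c[i], a_o[j], D[i][j]))
            denom = max(min_sep, sparse_c)
            validity = 0.0 if denom == 0 else (min_sep - sparse_c) / denom
        total += len(members) / n * validity
    return total


class TestDbcv:
    def test_agrees_with_oracle_on_random_instances(self):
        for trial in range(20):
            r = np.random.default_rng(trial)
            n = int(r.integers(10, 41))
            m = int(r.integers(1, 4))
            k = int(r.integers(2, 4))
            X = r.normal(size=(n, m))
            labels = r.integers(0, k, n)
            labels[: k] = np.arange(k)  # every cluster populated
            if r.random() < 0.3:
                labels[-2:] = -1  # some noise
            assert dbcv(X, labels) == pytest.approx(
                _oracle_dbcv(X, labels), abs=1e-9), f"trial {trial}"

    def test_separated_blobs_score_high(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(10, 0.3, (40, 2))])
        assert dbcv(X, np.repeat([0, 1], 40)) > 0.5

    def test_random_split_of_one_blob_scores_negative(self, rng):
        X = rng.normal(size=(60, 2))
        assert dbcv(X, rng.integers(0, 2, 60)) < 0

    def test_all_noise_rejected(self, rng):
        with pytest.raises(ValueError):
            dbcv(rng.normal(size=(10, 2)), np.full(10, -1))

    def test_single_cluster_is_not_positive(self, rng):
        X = rng.normal(size=(30, 2))
        assert dbcv(X, np.zeros(30, dtype=int)) <= 0.0


class TestPredictionStrength:
    def test_single_cluster_is_perfectly_stable(self, three_blobs):
        X, _ = three_blobs
        ps = prediction_strength(X, lambda Xs, s: pam(Xs, k=1, seed=s),
                                 n_repeats=3, seed=0)
        assert ps == 1.0

    def test_true_k_stable_overpartition_unstable(self, three_blobs):
        X, _ = three_blobs
        ps3 = prediction_strength(X, lambda Xs, s: pam(Xs, k=3, seed=s),
                                  n_repeats=10, seed=1)
        ps6 = prediction_strength(X, lambda Xs, s: pam(Xs, k=6, seed=s),
                                  n_repeats=10, seed=1)
        assert ps3 >= 0.95
        assert ps6 < 0.8
        assert ps6 < ps3

    def test_overpartition_degrades_across_seeds(self, rng):
        for s in range(5):
            r = np.random.default_rng(s)
            X = np.vstack([r.normal(i * 8, 0.4, (30, 2)) for i in range(2)])
            lo = prediction_strength(X, lambda Xs, sd: pam(Xs, k=2, seed=sd),
                                     n_repeats=4, seed=s)
            hi = prediction_strength(X, lambda Xs, sd: pam(Xs, k=4, seed=sd),
                                     n_repeats=4, seed=s)
            assert hi <= lo

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            prediction_strength(rng.normal(size=(10, 2)),
                                lambda Xs, s: pam(Xs, k=2, seed=s))


class TestConvexMetrics:
    def test_two_point_masses_limit(self):
        X = np.vstack([np.zeros((10, 2)), np.full((10, 2), 10.0)])
        X += np.random.default_rng(0).normal(0, 1e-6, X.shape)
        sil, db, _ = convex_metrics(X, np.repeat([0, 1], 10))
        assert sil > 0.999 and db < 1e-3

    def test_hand_computed_silhouette_two_pairs(self):
        # points 0,1 in cluster A at x=0,1; points 2,3 in cluster B at x=10,11
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        sil, db, ch = convex_metrics(X, labels)
        # per point: a=1, b=mean(10,11)=10.5 (or 9.5 by symmetry)
        expected = np.mean([(10.5 - 1) / 10.5, (9.5 - 1) / 9.5,
                            (9.5 - 1) / 9.5, (10.5 - 1) / 10.5])
        assert sil == pytest.approx(expected, abs=1e-12)

    def test_degenerate_identical_points_convention(self):
        X = np.ones((10, 2))
        with pytest.warns(UserWarning, match="coincide"):
            sil, _, _ = convex_metrics(X, np.repeat([0, 1], 5))
        assert sil == 0.0

    def test_single_cluster_undefined(self, rng):
        assert convex_metrics(rng.normal(size=(10, 2)),
                              np.zeros(10, int)) == (None, None, None)


class TestEntropy:
    def test_closed_forms(self):
        assert partition_entropy(np.repeat([0, 1], 50)) == pytest.approx(np.log(2))
        assert partition_entropy(np.zeros(10, int)) == 0.0
        h = partition_entropy(np.repeat([0, 1], [99, 1]))
        assert h == pytest.approx(0.0560, abs=1e-4)

    def test_bounds_and_noise_exclusion(self, rng):
        for _ in range(10):
            k = int(rng.integers(1, 6))
            labels = rng.integers(0, k, 100)
            labels[:k] = np.arange(k)
            h = partition_entropy(labels)
            assert 0.0 <= h <= np.log(k) + 1e-12
        with_noise = np.array([0, 0, 1, 1, -1, -1])
        assert partition_entropy(with_noise) == pytest.approx(np.log(2))


class TestEntropyProperties:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=-1, max_value=5), min_size=2,
                    max_size=60).filter(lambda ls: any(l >= 0 for l in ls)))
    def test_entropy_bounded_by_log_k(self, labels):
        labels = np.asarray(labels)
        h = partition_entropy(labels)
        k = len(set(labels[labels >= 0]))
        assert -1e-12 <= h <= np.log(max(k, 1)) + 1e-12
        assert (h == 0.0) == (k <= 1)


class TestGateAndSelection:
    def test_density_pair_passes_convex_fails(self):
        m = PartitionMetrics(dbcv=0.22, prediction_strength=1.00,
                             silhouette=0.17, davies_bouldin=1.02,
                             entropy=0.06, min_mass=0.02, k=2)
        m = gate(m)
        assert m.pass_density_pair and not m.pass_convex_pair
        assert not m.balanced and not m.pass_all

    def test_convex_pair_passes_density_fails(self):
        m = gate(PartitionMetrics(dbcv=-0.86, prediction_strength=0.94,
                                  silhouette=0.74, davies_bouldin=0.49,
                                  entropy=0.06, min_mass=0.06, k=2))
        assert m.pass_convex_pair and not m.pass_density_pair and not m.pass_all

    def test_thresholds_are_inclusive_except_dbcv(self):
        at = gate(PartitionMetrics(dbcv=1e-12, prediction_strength=0.8,
                                   silhouette=0.5, davies_bouldin=0.6,
                                   min_mass=0.05, k=2))
        assert at.pass_all
        zero_dbcv = gate(PartitionMetrics(dbcv=0.0, prediction_strength=0.9,
                                          silhouette=0.6, davies_bouldin=0.5,
                                          min_mass=0.2, k=2))
        assert not zero_dbcv.pass_density_pair

    def _passing(self, labels, entropy, k=2):
        p = Partition(labels=np.asarray(labels), method="pam", hyperparams={})
        m = gate(PartitionMetrics(dbcv=0.5, prediction_strength=0.9,
                                  silhouette=0.7, davies_bouldin=0.3,
                                  entropy=entropy, min_mass=0.3, k=k))
        return p, m

    def test_highest_entropy_selected_among_equal_k(self):
        a = self._passing([0, 0, 0, 1], 0.06)
        b = self._passing([0, 0, 1, 1], 0.09)
        rep = select_best([a, b], selection="entropy")
        assert rep["verdict"] == "clusters-found"
        assert rep["selected"]["entropy"] == pytest.approx(0.09)

    def test_balance_selection_prefers_true_k_over_oversplit(self):
        balanced3 = self._passing([0, 0, 1, 1, 2, 2], np.log(3), k=3)
        oversplit6 = self._passing([0, 1, 2, 3, 4, 5], np.log(6), k=6)
        rep = select_best([balanced3, oversplit6])
        assert rep["selected"]["k"] == 3

    def test_empty_passing_set_verdict(self):
        p = Partition(labels=np.array([0, 0, 1, 1]), method="pam", hyperparams={})
        m = gate(PartitionMetrics(dbcv=-0.5, prediction_strength=0.9,
                                  silhouette=0.2, davies_bouldin=1.2,
                                  min_mass=0.5, k=2))
        rep = select_best([(p, m)])
        assert rep["verdict"] == "no plausible partition"
        assert rep["selected"] is None
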