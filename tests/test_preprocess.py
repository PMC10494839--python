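"""Table IO, aggregation, normalization, filtering, and the four distances."""

import numpy as np
import pandas as pd
import pytest

from enteromap import (AbundanceTable, aggregate_taxonomy, filter_taxa,
                       normalize_tss, pairwise_distances, read_abundance_table,
                       remove_dominated)


class TestReadTable:
    def test_orientation_roundtrip(self, tmp_path):
        df = pd.DataFrame(np.arange(12).reshape(3, 4) + 1.0,
                          index=[f"t{i}" for i in range(3)],
                          columns=[f"s{j}" for j in range(4)])
        path = tmp_path / "taxa_rows.tsv"
        df.to_csv(path, sep="\t")
        t = read_abundance_table(path, orientation="taxa-in-rows")
        assert t.n == 4 and t.d == 3
        assert t.sample_ids == ["s0", "s1", "s2", "s3"]
        np.testing.assert_array_equal(t.matrix, df.values.T)

    def test_negative_entry_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        pd.DataFrame([[0.5, -0.1]], index=["s1"], columns=["a", "b"]).to_csv(
            path, sep="\t")
        with pytest.raises(ValueError, match="negative"):
            read_abundance_table(path)

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample\ta\tb\ns1\t0.5\toops\n")
        with pytest.raises(ValueError, match="b"):
            read_abundance_table(path)


class TestAggregation:
    def test_additivity_and_rest_pooling(self, toy_table):
        agg = aggregate_taxonomy(toy_table, "Genus")
        assert agg.taxon_ids == ["Bacteroides", "Ruminococcus", "Rest"]
        # two Bacteroides OTUs with 0.2 and 0.3 in sample s1 sum to 0.5
        assert agg.matrix[0, 0] == pytest.approx(0.5)
        # the g__ (unassigned) OTU lands in Rest
        assert agg.matrix[0, 2] == pytest.approx(0.4)

    def test_mass_conserved(self, toy_table):
        agg = aggregate_taxonomy(toy_table, "Family")
        np.testing.assert_allclose(agg.matrix.sum(axis=1),
                                   toy_table.matrix.sum(axis=1), atol=1e-9)

    def test_missing_lineages_rejected(self):
        t = AbundanceTable(sample_ids=["s"], taxon_ids=["a"], matrix=[[1.0]])
        with pytest.raises(ValueError, match="lineage"):
            aggregate_taxonomy(t, "Genus")


class TestNormalize:
    def test_arithmetic_and_idempotence(self):
        t = AbundanceTable(sample_ids=["s"], taxon_ids=list("abc"),
                           matrix=[[2.0, 2.0, 4.0]])
        norm = normalize_tss(t)
        np.testing.assert_allclose(norm.matrix, [[0.25, 0.25, 0.5]])
        again = normalize_tss(norm)
        np.testing.assert_allclose(again.matrix, norm.matrix, atol=1e-12)

    def test_zero_row_named(self):
        t = AbundanceTable(sample_ids=["good", "empty"], taxon_ids=["a"],
                           matrix=[[1.0], [0.0]])
        with pytest.raises(ValueError, match="empty"):
            normalize_tss(t)


class TestFilter:
    def test_prevalence_and_std_rules(self, rng):
        n = 200
        common = rng.dirichlet(np.ones(3), size=n)
        rare = np.zeros((n, 1)); rare[0, 0] = 0.01          # 0.5% < 1%
        constant = np.full((n, 1), 0.005)                    # std 0 < 0.001
        t = AbundanceTable(
            sample_ids=[f"s{i}" for i in range(n)],
            taxon_ids=["a", "b", "c", "rare", "const"],
            matrix=np.hstack([common, rare, constant]))
        kept, report = filter_taxa(normalize_tss(t))
        assert kept.taxon_ids == ["a", "b", "c"]
        assert set(report.taxon_id) == {"rare", "const"}
        assert report.set_index("taxon_id").loc["const", "low_std"]

    def test_threshold_ties_retained(self):
        # prevalence exactly 1% and std exactly at the cut are kept ("less than")
        n = 100
        m = np.ones((n, 2)) * 0.5
        m[1:, 1] = 0.0; m[0, 1] = 0.5  # taxon b present in exactly 1 of 100
        t = AbundanceTable(sample_ids=[f"s{i}" for i in range(n)],
                           taxon_ids=["a", "b"], matrix=m)
        kept, _ = filter_taxa(t, min_prevalence=0.01, min_std=0.0)
        assert "b" in kept.taxon_ids

    def test_all_dropped_is_an_error(self):
        t = AbundanceTable(sample_ids=["s1", "s2"], taxon_ids=["a"],
                           matrix=[[0.5], [0.5]])
        with pytest.raises(ValueError):
            filter_taxa(t, min_prevalence=0.0, min_std=0.5)


class TestRemoveDominated:
    def test_default_policy_drops_dominated_sample(self):
        t = AbundanceTable(sample_ids=["dom", "ok"], taxon_ids=list("abc"),
                           matrix=[[0.8, 0.1, 0.1], [0.5, 0.3, 0.2]])
        out = remove_dominated(t, threshold=0.7)
        assert out.sample_ids == ["ok"]

    def test_threshold_one_is_vacuous(self):
        t = AbundanceTable(sample_ids=["s"], taxon_ids=list("ab"),
                           matrix=[[0.9, 0.1]])
        out = remove_dominated(t, threshold=1.0)
        np.testing.assert_array_equal(out.matrix, t.matrix)
        with pytest.raises(ValueError):
            remove_dominated(t, threshold=0.0)


class TestDistances:
    def test_closed_forms(self):
        t = AbundanceTable(sample_ids=["x", "y", "z"], taxon_ids=["a", "b"],
                           matrix=[[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        bc = pairwise_distances(t, "braycurtis").values
        l1 = pairwise_distances(t, "manhattan").values
        js = pairwise_distances(t, "jensenshannon").values
        assert bc[0, 1] == pytest.approx(1.0)
        assert l1[0, 1] == pytest.approx(2.0)
        assert js[0, 1] == pytest.approx(np.sqrt(np.log(2)), abs=1e-12)
        for D in (bc, l1, js):
            assert D[0, 2] == pytest.approx(0.0)  # identical rows

    def test_unknown_metric(self, toy_table):
        with pytest.raises(ValueError):
            pairwise_distances(toy_table, "cosine")

    @pytest.mark.parametrize("metric", ["manhattan", "euclidean",
                                        "braycurtis", "jensenshannon"])
    def test_metric_axioms_on_simplex_triples(self, metric, rng):
        X = rng.dirichlet(np.ones(5) * 0.5, size=30)
        t = AbundanceTable(sample_ids=[f"s{i}" for i in range(30)],
                           taxon_ids=[f"t{j}" for j in range(5)], matrix=X)
        D = pairwise_distances(t, metric).values
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        assert np.all(np.diag(D) == 0) and (D >= 0).all()
        for _ in range(50):
            i, j, k = rng.choice(30, 3, replace=False)
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-12
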