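import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spotcount.genes import filter_genes, run_gene_panel
from spotcount.grouping import (
    ClusterAssignment,
    before_after_ratios,
    cluster_locations,
    cluster_pipeline,
    cluster_specific_panel,
    embed_pca,
    normalize_log,
    select_hvg,
)
from spotcount.matrix import CountMatrix
from spotcount.simulate import simulate_cluster_mixture


class TestNormalizeLog:
    def test_hand_values(self):
        # column sums: N = [100, 100]; entries chosen to hit the oracle cases
        counts = np.array([[0, 100], [100, 0]])
        x = normalize_log(CountMatrix(counts))
        assert x[0, 0] == 0.0
        assert x[0, 1] == pytest.approx(np.log(1 + 1e4))
        counts = np.array([[1, 0], [99, 100]])
        x = normalize_log(CountMatrix(counts))
        assert x[0, 0] == pytest.approx(np.log(101))

    def test_monotone_in_counts(self):
        counts = np.array([[0, 1, 5], [10, 9, 5]])  # constant column sums
        x = normalize_log(CountMatrix(counts))
        assert x[0, 0] < x[0, 1] < x[0, 2]

    def test_gene_order_invariance(self):
        r = np.random.default_rng(0)
        counts = r.poisson(3, size=(6, 8)) + 1
        m = CountMatrix(counts)
        x = normalize_log(m)
        perm = [3, 1, 5, 0, 2, 4]
        xp = normalize_log(m.subset_genes(perm))
        assert np.allclose(x[perm], xp)


class TestSelectHvg:
    def test_all_returned_when_few_genes(self, poisson_matrix):
        m = poisson_matrix(G=100, n=50)
        assert select_hvg(m, n_top=2000) == m.gene_ids

    def test_spiked_gene_ranked_first(self):
        r = np.random.default_rng(1)
        G, n = 300, 200
        counts = r.poisson(2.0, size=(G, n))
        # same mean (2) as the bulk but ~18x the Poisson variance
        counts[7] = np.where(r.random(n) < 0.1, 20, 0)
        m = CountMatrix(counts)
        top = select_hvg(m, n_top=10)
        assert top[0] == m.gene_ids[7]

    def test_deterministic(self):
        r = np.random.default_rng(2)
        m = CountMatrix(r.poisson(2.0, size=(100, 80)))
        assert select_hvg(m, n_top=30) == select_hvg(m, n_top=30)


class TestEmbedPca:
    def test_rank_one_data(self):
        u = np.linspace(-1, 1, 50)
        x = np.outer(np.arange(1, 6), u)  # 5 genes, rank 1
        scores = embed_pca(x, n_pcs=3)
        total = (scores**2).sum()
        assert (scores[:, 0] ** 2).sum() / total > 0.999

    def test_score_columns_orthogonal_and_ordered(self):
        r = np.random.default_rng(3)
        x = r.normal(size=(20, 100))
        scores = embed_pca(x, n_pcs=5)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        norms = np.diag(gram)
        assert np.all(np.diff(norms) <= 1e-8)

    def test_npcs_reduced_when_rank_deficient(self):
        x = np.random.default_rng(4).normal(size=(3, 30))
        scores = embed_pca(x, n_pcs=15)
        assert scores.shape == (30, 3)


class TestClusterLocations:
    def test_two_separated_blobs(self):
        r = np.random.default_rng(5)
        a = r.normal(0, 1, size=(200, 15))
        b = r.normal(10, 1, size=(200, 15))
        scores = np.vstack([a, b])
        truth = np.repeat([0, 1], 200)
        ca = cluster_locations(scores, seed=0)
        assert ca.n_clusters == 2
        assert adjusted_rand_score(truth, ca.labels) == 1.0

    def test_single_blob_modal_outcome_one_cluster(self):
        r = np.random.default_rng(6)
        scores = r.normal(size=(150, 15))
        outcomes = [cluster_locations(scores, seed=s).n_clusters for s in range(10)]
        assert max(set(outcomes), key=outcomes.count) == 1

    def test_row_order_invariant_quality(self):
        r = np.random.default_rng(7)
        scores = np.vstack(
            [r.normal(0, 1, size=(100, 10)), r.normal(8, 1, size=(100, 10))]
        )
        truth = np.repeat([0, 1], 100)
        perm = r.permutation(200)
        ari1 = adjusted_rand_score(truth, cluster_locations(scores, seed=1).labels)
        ari2 = adjusted_rand_score(
            truth[perm], cluster_locations(scores[perm], seed=1).labels
        )
        assert ari1 == pytest.approx(ari2)

    def test_too_few_locations_rejected(self):
        with pytest.raises(ValueError, match="k_neighbors"):
            cluster_locations(np.zeros((10, 5)), k_neighbors=20)


@pytest.fixture(scope="module")
def mixture():
    r = np.random.default_rng(8)
    G, K = 60, 3
    rates = r.uniform(0.5, 3, size=(K, G)) * r.choice([0.3, 1.0, 3.0], size=(K, G))
    m, labels, _ = simulate_cluster_mixture(K, rates, [120, 120, 120], seed=9)
    return filter_genes(m), labels


class TestClusterRecoveryAndPanels:
    def test_pipeline_recovers_true_labels(self, mixture):
        m, labels = mixture
        ca = cluster_pipeline(m, seed=0)
        assert adjusted_rand_score(labels, ca.labels) >= 0.9

    def test_within_cluster_overdispersion_vanishes(self, mixture):
        m, labels = mixture
        whole = run_gene_panel(m)
        panels = cluster_specific_panel(m, ClusterAssignment(labels))
        assert whole["sig_p_nb"].mean() >= 0.5
        for p in panels.values():
            assert p["sig_p_nb"].mean() <= 0.01

    def test_single_cluster_equals_whole_panel(self, mixture):
        m, _ = mixture
        sub = m.subset_locations(np.arange(60))
        sub = filter_genes(sub)
        whole = run_gene_panel(sub)
        panels = cluster_specific_panel(sub, ClusterAssignment(np.zeros(60, dtype=int)))
        pd.testing.assert_frame_equal(whole, panels[0])

    def test_small_clusters_skipped(self, mixture):
        m, labels = mixture
        lab = labels.copy()
        lab[:5] = 3  # a 5-location pseudo-cluster (below min size)
        panels = cluster_specific_panel(m, ClusterAssignment(lab), min_cluster_size=20)
        assert 3 not in panels or len(panels) == 3

    def test_all_zero_genes_within_cluster_absent(self):
        counts = np.zeros((2, 60), dtype=int)
        counts[0, :] = 2
        counts[1, 30:] = 3  # gene1 silent in cluster 0
        m = CountMatrix(counts)
        labels = np.repeat([0, 1], 30)
        panels = cluster_specific_panel(m, ClusterAssignment(labels), min_cluster_size=10)
        assert list(panels[0]["gene"]) == ["gene0"]
        assert set(panels[1]["gene"]) == {"gene0", "gene1"}


class TestRatios:
    def test_identical_tables_give_unit_ratios(self, mixture):
        m, _ = mixture
        sub = filter_genes(m.subset_locations(np.arange(80)))
        panel = run_gene_panel(sub)
        table, medians = before_after_ratios(panel, {0: panel})
        defined = table["ratio"].dropna()
        assert np.allclose(defined, 1.0)

    def test_zero_before_omitted_from_median(self):
        panel = pd.DataFrame(
            {
                "gene": ["a", "b"],
                "error": ["", ""],
                "preferred_family": ["poisson", "poisson"],
                **{f"sig_{t}": [False, False] for t in ("p_zip", "p_nb", "nb_zinb", "zip_zinb")},
            }
        )
        after = panel.copy()
        after["preferred_family"] = ["nb", "nb"]
        table, medians = before_after_ratios(panel, {0: after})
        assert medians["prefer_nb"] is None  # before-proportion was zero
        assert medians["prefer_poisson"] == pytest.approx(0.0)

    def test_mixture_direction(self, mixture):
        m, labels = mixture
        whole = run_gene_panel(m)
        panels = cluster_specific_panel(m, ClusterAssignment(labels))
        _, medians = before_after_ratios(whole, panels)
        assert medians["prefer_poisson"] > 1.0
        assert medians["prefer_nb"] < 1.0

    def test_location_partition_covers_all(self, mixture):
        m, labels = mixture
        ca = ClusterAssignment(labels)
        idx = np.concatenate(
            [np.flatnonzero(ca.labels == c) for c in range(ca.n_clusters)]
        )
        assert sorted(idx) == list(range(m.n_locations))
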