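"""Subsampling, embedding, kNN graph, Louvain and composition tables."""

import warnings

import igraph as ig
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

import gliaquant as gq
from gliaquant.cluster import SubsampleError
from gliaquant.config import ConfigError, GroupSpec, SimulationConfig

from conftest import brute_force_knn


class TestSubsample:
    def test_balanced_counts(self, cohort):
        _, cells, _ = cohort
        sub = gq.subsample_balanced(cells, 200, seed=0)
        counts = sub.groupby(["group", "region"]).size()
        assert (counts == 200).all() and len(counts) == 4

    def test_undersized_subgroup_named_in_error(self, cohort):
        _, cells, _ = cohort
        with pytest.raises(SubsampleError, match="control.*hippocampus"):
            gq.subsample_balanced(cells, len(cells), seed=0)

    def test_seed_reproducible(self, cohort):
        _, cells, _ = cohort
        a = gq.subsample_balanced(cells, 150, seed=5)
        b = gq.subsample_balanced(cells, 150, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = gq.subsample_balanced(cells, 150, seed=6)
        assert set(a.cell_id) != set(c.cell_id)

    def test_without_replacement(self, cohort):
        _, cells, _ = cohort
        sub = gq.subsample_balanced(cells, 300, seed=1)
        assert sub.cell_id.is_unique


class TestLogTransform:
    def test_natural_log_and_shape(self):
        df = pd.DataFrame({m: [np.e] for m in gq.MARKERS})
        x = gq.log_transform(df)
        assert x.shape == (1, 5)
        np.testing.assert_allclose(x, 1.0)

    def test_column_order_fixed(self):
        df = pd.DataFrame({m: [float(i + 2)] for i, m in enumerate(gq.MARKERS)})
        shuffled = df[list(reversed(gq.MARKERS))]
        np.testing.assert_allclose(gq.log_transform(shuffled), np.log(df.to_numpy()))

    def test_zero_variance_column_preserved(self):
        df = pd.DataFrame({m: [5.0, 5.0, 5.0] for m in gq.MARKERS})
        x = gq.log_transform(df)
        assert np.ptp(x[:, 2]) == 0.0

    def test_negative_rejected_zero_pseudocounted(self):
        df = pd.DataFrame({m: [1.0, -1.0] for m in gq.MARKERS})
        with pytest.raises(ValueError, match="negative"):
            gq.log_transform(df)
        df2 = pd.DataFrame({m: [0.0, 1.0] for m in gq.MARKERS})
        with pytest.warns(UserWarning, match="pseudocount"):
            x = gq.log_transform(df2)
        assert x[0, 0] == 0.0  # log(0 + 1)


class TestTsne:
    def test_learning_rate_rule(self):
        cfg = gq.EmbeddingConfig(n_per_group=1200, ee_factor=12.0)
        assert cfg.learning_rate(1200) == pytest.approx(100.0)

    def test_output_shape_and_finiteness(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(300, 5))
        with pytest.warns(UserWarning, match="perplexity"):
            emb = gq.tsne_embed(feats, gq.EmbeddingConfig(n_per_group=300, seed=0))
        assert emb.shape == (300, 2)
        assert np.isfinite(emb).all()

    def test_nan_features_rejected(self):
        feats = np.full((50, 5), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            gq.tsne_embed(feats, gq.EmbeddingConfig(n_per_group=50, perplexity=10))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separated_gaussians_keep_structure(self, seed):
        """Three 5D Gaussian phenotypes at >= 6 sd separation stay separated
        in the embedding: silhouette of the true labels > 0.5."""
        rng = np.random.default_rng(seed)
        centres = np.array(
            [[0, 0, 0, 0, 0], [6, 6, 0, 0, 0], [0, 6, 6, 6, 0]], dtype=float
        )
        labels = rng.integers(0, 3, size=3000)
        feats = centres[labels] + rng.normal(size=(3000, 5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = gq.tsne_embed(
                feats, gq.EmbeddingConfig(n_per_group=3000, perplexity=250, seed=seed)
            )
        assert silhouette_score(emb, labels) > 0.5


class TestKnnGraph:
    def test_default_k_floor_sqrt(self):
        rng = np.random.default_rng(1)
        g = gq.knn_graph(rng.normal(size=(9, 2)))
        degs = np.array(g.degree())
        assert degs.min() >= 3  # k = floor(sqrt(9)) = 3, union-symmetrised
        assert int(np.floor(np.sqrt(124_800))) == 353

    def test_line_matches_brute_force(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        g = gq.knn_graph(pts, k=3)
        assert set(map(tuple, g.get_edgelist())) == brute_force_knn(pts, 3)

    def test_random_points_match_brute_force(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(200, 2))
        k = int(np.floor(np.sqrt(200)))
        g = gq.knn_graph(pts, chunk=64)  # multiple chunks exercised
        assert set(map(tuple, g.get_edgelist())) == brute_force_knn(pts, k)

    def test_bad_k_rejected(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ConfigError):
            gq.knn_graph(pts, k=0)
        with pytest.raises(ConfigError):
            gq.knn_graph(np.random.default_rng(0).normal(size=(5, 2)), k=5)


class TestLouvain:
    def test_two_cliques_two_communities(self):
        g = ig.Graph.Full(10) + ig.Graph.Full(10)
        labels, q = gq.louvain_cluster(g, seed=0)
        assert labels.max() == 2
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert set(labels[:10]) != set(labels[10:])

    def test_single_node(self):
        labels, _ = gq.louvain_cluster(ig.Graph(n=1), seed=0)
        assert list(labels) == [1]

    def test_modularity_matches_direct_q(self):
        """Reported modularity equals the direct Q = sum_c (e_c/m - (d_c/2m)^2)
        computation on a 30-node random graph."""
        rng = np.random.default_rng(3)
        g = ig.Graph.Erdos_Renyi(n=30, p=0.2)
        labels, q = gq.louvain_cluster(g, seed=1)
        m = g.ecount()
        q_direct = 0.0
        for c in np.unique(labels):
            nodes = set(np.flatnonzero(labels == c))
            e_c = sum(1 for a, b in g.get_edgelist() if a in nodes and b in nodes)
            d_c = sum(g.degree(v) for v in nodes)
            q_direct += e_c / m - (d_c / (2 * m)) ** 2
        assert q == pytest.approx(q_direct, abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            gq.louvain_cluster(ig.Graph(n=0), seed=0)


class TestCompositionTables:
    @pytest.fixture()
    def toy(self):
        return pd.DataFrame(
            {
                "cell_id": [str(i) for i in range(10)],
                "case_id": ["a"] * 4 + ["b"] * 6,
                "group": ["control"] * 4 + ["disease"] * 6,
                "region": ["motor_cortex"] * 10,
                "cluster": [1, 1, 2, 3, 1, 2, 2, 2, 3, 3],
            }
        )

    def test_group_contribution_counting_oracle(self, toy):
        out = gq.cluster_group_contribution(toy)
        # cluster 1: 2 control, 1 disease; cluster 2: 1 + 3; cluster 3: 1 + 2
        assert out.loc[1, "control"] == pytest.approx(100 * 2 / 3)
        assert out.loc[2, "disease"] == pytest.approx(75.0)
        np.testing.assert_allclose(out.sum(axis=1), 100.0)

    def test_pure_cluster_contribution(self, toy):
        toy2 = toy.assign(cluster=[1, 1, 1, 1, 2, 2, 2, 2, 2, 2])
        out = gq.cluster_group_contribution(toy2)
        assert out.loc[1, "control"] == 100.0 and out.loc[1, "disease"] == 0.0

    def test_case_percentages_counting_oracle(self, toy):
        out = gq.cluster_case_percentages(toy)
        a1 = out[(out.case_id == "a") & (out.cluster == 1)]["pct"].iloc[0]
        assert a1 == pytest.approx(50.0)
        sums = out.groupby("case_id")["pct"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_case_in_single_cluster(self, toy):
        toy2 = toy.assign(cluster=[1] * 4 + [2] * 6)
        out = gq.cluster_case_percentages(toy2)
        assert out[(out.case_id == "a")]["pct"].iloc[0] == 100.0


class TestRelativeMoiHigh:
    def _table(self):
        rng = np.random.default_rng(5)
        n = 400
        df = pd.DataFrame(
            {
                "cell_id": [str(i) for i in range(n)],
                "case_id": rng.choice(["a", "b"], n),
                "cluster": rng.integers(1, 5, n),
            }
        )
        for m in gq.MARKERS:
            df[f"{m}_high"] = rng.random(n) < 0.3
        return df

    def test_cluster_equal_to_overall_gives_zero(self):
        df = pd.DataFrame(
            {
                "cell_id": list("abcd"),
                "case_id": ["c1"] * 4,
                "cluster": [1, 1, 2, 2],
            }
        )
        for m in gq.MARKERS:
            df[f"{m}_high"] = [True, False, True, False]  # 50% everywhere
        rel = gq.relative_moi_high(df)
        np.testing.assert_allclose(rel["rel_pct_high"], 0.0)

    def test_enriched_cluster_positive_difference(self):
        df = pd.DataFrame(
            {
                "cell_id": [str(i) for i in range(10)],
                "case_id": ["c1"] * 10,
                "cluster": [1] * 5 + [2] * 5,
            }
        )
        # case overall 50% high; cluster 1 has 80%
        flags = [True, True, True, True, False, True, False, False, False, False]
        for m in gq.MARKERS:
            df[f"{m}_high"] = flags
        rel = gq.relative_moi_high(df)
        c1 = rel[(rel.cluster == 1) & (rel.marker == "CD68")]["rel_pct_high"].iloc[0]
        assert c1 == pytest.approx(30.0)

    def test_weighted_mean_is_zero_identity(self):
        """Weighting each cluster's relative percentage by the case's cell
        share in that cluster must give exactly 0 — the defining identity
        of the difference normalisation."""
        df = self._table()
        rel = gq.relative_moi_high(df)
        sizes = df.groupby(["case_id", "cluster"]).size().rename("n").reset_index()
        totals = sizes.groupby("case_id")["n"].transform("sum")
        sizes["w"] = sizes["n"] / totals
        merged = rel.merge(sizes, on=["case_id", "cluster"])
        wm = merged.groupby(["case_id", "marker"]).apply(
            lambda d: np.sum(d.rel_pct_high * d.w), include_groups=False
        )
        np.testing.assert_allclose(wm, 0.0, atol=1e-9)

    def test_missing_flags_rejected(self):
        with pytest.raises(ValueError, match="flags"):
            gq.relative_moi_high(pd.DataFrame({"cluster": [1], "case_id": ["a"]}))


class TestPlantedPhenotypeRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_feature_space_louvain_recovers_phenotypes(self, seed):
        """kNN-Louvain on the 5D log-feature space recovers 4 planted
        well-separated phenotypes (>= 4 log-sd) with ARI >= 0.8."""
        fracs = {
            "pan_low": 0.25,
            "cd68_high": 0.25,
            "hladr_cd74_high": 0.25,
            "iba1_high": 0.25,
        }
        cfg = SimulationConfig(
            groups=[
                GroupSpec("control", "motor_cortex", 1, fracs),
                GroupSpec("disease", "motor_cortex", 1, fracs),
            ],
            cells_per_case=2000,
        )
        cells, truth = gq.generate_cell_table(cfg, seed)
        feats = gq.log_transform(cells)
        labels, _ = gq.louvain_cluster(gq.knn_graph(feats), seed=seed)
        truth_map = dict(zip(truth.cells.cell_id, truth.cells.phenotype))
        planted = [truth_map[c] for c in cells.cell_id]
        assert adjusted_rand_score(planted, labels) >= 0.8


def test_full_run_composition_invariants(clustered):
    result, _ = clustered
    assert result.k == int(np.floor(np.sqrt(len(result.cells))))
    assert set(result.cells["cluster"]) == set(range(1, result.n_clusters + 1))
    contrib = gq.cluster_group_contribution(result.cells)
    np.testing.assert_allclose(contrib.sum(axis=1), 100.0, atol=1e-9)
    pct = gq.cluster_case_percentages(result.cells)
    np.testing.assert_allclose(pct.groupby("case_id")["pct"].sum(), 100.0, atol=1e-9)
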