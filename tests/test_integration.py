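import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from devodyn.integration import (
    classify_correlation, cluster_overlap_test, genewise_correlation,
    group_clusters_kmeans, pearson_with_p, timepointwise_correlation, tp_index,
)

TPS = ["E1", "E2", "L1", "L2", "P1", "P2", "A1", "A2"]
STAGE_OF = {"E1": "egg", "E2": "egg", "L1": "larva", "L2": "larva",
            "P1": "pupa", "P2": "pupa", "A1": "adult", "A2": "adult"}


def random_frame(n, cols, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols,
                        index=[f"g{i}" for i in range(n)])


class TestTimepointwise:
    def test_identical_matrices_unit_diagonal(self):
        x = random_frame(100, TPS, 0)
        corr = timepointwise_correlation(x, x)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)

    def test_independent_matrices_near_zero(self):
        corr = timepointwise_correlation(random_frame(1000, TPS, 1),
                                         random_frame(1000, TPS, 2))
        assert np.median(np.abs(corr.to_numpy())) < 0.05

    def test_matches_per_cell_pearson_oracle(self):
        a = random_frame(60, TPS, 3)
        b = random_frame(60, TPS, 4)
        corr = timepointwise_correlation(a, b)
        for i in (0, 3, 7):
            for j in (1, 5):
                expected = stats.pearsonr(a.iloc[:, i], b.iloc[:, j]).statistic
                assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_shared_genes_rejected(self):
        a = random_frame(2, TPS, 5)
        with pytest.raises(ValueError, match="fewer than"):
            timepointwise_correlation(a, a)


class TestGenewise:
    def test_identical_profiles_positive(self):
        x = random_frame(20, TPS, 6)
        gw = genewise_correlation(x, x)
        np.testing.assert_allclose(gw["R"], 1.0, atol=1e-12)
        assert (gw["class"] == "positive").all()

    def test_negated_profiles_negative(self):
        x = random_frame(20, TPS, 7)
        gw = genewise_correlation(x, -x)
        np.testing.assert_allclose(gw["R"], -1.0, atol=1e-12)
        assert (gw["class"] == "negative").all()

    def test_constant_protein_profile_is_none(self):
        x = random_frame(3, TPS, 8)
        y = x.copy()
        y.iloc[0] = 5.0
        gw = genewise_correlation(x, y)
        assert gw["class"].iloc[0] == "none" and np.isnan(gw["R"].iloc[0])

    def test_p_value_matches_t_transform(self):
        x = random_frame(50, TPS, 9)
        y = random_frame(50, TPS, 10)
        gw = genewise_correlation(x, y)
        for g in gw.index[:10]:
            expected = stats.pearsonr(x.loc[g], y.loc[g])
            assert gw.loc[g, "R"] == pytest.approx(expected.statistic, abs=1e-12)
            assert gw.loc[g, "p"] == pytest.approx(expected.pvalue, rel=1e-9)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="share timepoints"):
            genewise_correlation(random_frame(5, TPS, 0),
                                 random_frame(5, TPS[:4], 0))


class TestTPIndex:
    def _layers(self, tx_pattern, prot_pattern, n=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        tx = pd.DataFrame(np.tile(tx_pattern, (n, 1)) + rng.normal(0, noise, (n, 8)),
                          columns=TPS, index=[f"g{i}" for i in range(n)])
        prot = pd.DataFrame(np.tile(prot_pattern, (n, 1)) + rng.normal(0, noise, (n, 8)),
                            columns=TPS, index=tx.index)
        return tx, prot

    def test_identical_layers_give_zero_index(self):
        tx, prot = self._layers(np.arange(8.0), np.arange(8.0))
        assignment = pd.Series(0, index=tx.index)
        idx = tp_index(assignment, tx, prot, STAGE_OF)
        np.testing.assert_allclose(idx.to_numpy(), 0.0, atol=1e-12)

    def test_opposed_egg_layers_give_index_two(self):
        tx_pat = np.array([1.0, 1.0, 0, 0, 0, 0, 0, 0])
        prot_pat = np.array([-1.0, -1.0, 0, 0, 0, 0, 0, 0])
        tx, prot = self._layers(tx_pat, prot_pat)
        idx = tp_index(pd.Series(0, index=tx.index), tx, prot, STAGE_OF)
        assert idx.loc[0, "egg"] == pytest.approx(2.0)
        assert idx.loc[0, "larva"] == pytest.approx(0.0)

    def test_antisymmetric_under_layer_swap(self):
        tx, prot = self._layers(np.arange(8.0), np.arange(8.0)[::-1], noise=0.3)
        assignment = pd.Series([0, 0, 0, 1, 1, 1], index=tx.index)
        fwd = tp_index(assignment, tx, prot, STAGE_OF)
        rev = tp_index(assignment, prot, tx, STAGE_OF)
        pd.testing.assert_frame_equal(fwd, -rev)


class TestKMeansGrouping:
    def test_recovers_four_archetype_groups(self):
        archetypes = np.array([[2.0, 2, -2, 2], [2, -1, -1, 2],
                               [-2, 2, 2, -2], [0, 0, 0, 0]])
        rows = np.repeat(archetypes, 3, axis=0)
        rng = np.random.default_rng(1)
        idx = pd.DataFrame(rows + rng.normal(0, 0.05, rows.shape),
                           columns=["egg", "larva", "pupa", "adult"])
        groups = group_clusters_kmeans(idx, k=4, seed=0)
        truth = np.repeat(np.arange(4), 3)
        assert adjusted_rand_score(truth, groups.to_numpy()) == 1.0

    def test_k_equals_rows_gives_singletons(self):
        idx = pd.DataFrame(np.eye(4) * 3)
        groups = group_clusters_kmeans(idx, k=4, seed=0)
        assert groups.nunique() == 4

    def test_deterministic_under_seed(self):
        idx = pd.DataFrame(np.random.default_rng(2).normal(size=(10, 4)))
        a = group_clusters_kmeans(idx, k=3, seed=5)
        b = group_clusters_kmeans(idx, k=3, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_k_larger_than_rows_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            group_clusters_kmeans(pd.DataFrame(np.eye(3)), k=4)


class TestClusterOverlap:
    def test_identical_memberships_minimal_p_on_diagonal(self):
        genes = [f"g{i}" for i in range(60)]
        assign = pd.Series(np.repeat([0, 1, 2], 20), index=genes)
        out = cluster_overlap_test(assign, assign)
        diag = out[out["tx_cluster"] == out["prot_cluster"]]
        off = out[out["tx_cluster"] != out["prot_cluster"]]
        assert diag["p"].max() < off["p"].min()
        # hypergeometric oracle for one diagonal cell
        expected = stats.hypergeom.sf(19, 60, 20, 20)
        assert diag["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_clusters_one_tailed_p_is_one(self):
        genes = [f"g{i}" for i in range(40)]
        a = pd.Series(np.repeat([0, 1], 20), index=genes)
        b = pd.Series(np.repeat([1, 0], 20), index=genes)
        out = cluster_overlap_test(a, b)
        # pair (0, 0) shares no genes: zero overlap -> one-tailed p = 1
        disjoint = out[(out["tx_cluster"] == 0) & (out["prot_cluster"] == 0)]
        assert disjoint["p"].iloc[0] == pytest.approx(1.0)

    def test_null_memberships_bh_significance_near_nominal(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(400)]
        sig = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = pd.Series(r.integers(0, 4, 400), index=genes)
            b = pd.Series(r.integers(0, 4, 400), index=genes)
            out = cluster_overlap_test(a, b)
            sig.append((out["fdr"] < 0.05).mean())
        assert np.mean(sig) < 0.05

    def test_empty_universe_rejected(self):
        a = pd.Series([0], index=["x"])
        b = pd.Series([0], index=["y"])
        with pytest.raises(ValueError, match="empty"):
            cluster_overlap_test(a, b)
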