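"""Cluster permutation machinery, rank correlations and effect sizes."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from sospindle import (MONTAGE_11, cluster_corrected_spearman,
                       cluster_permutation_test, cohens_d, cohens_d_cluster,
                       montage_adjacency, partial_spearman)
from sospindle.montage import Adjacency
from sospindle.stats import _rho_to_t, grid_adjacency

ADJ = montage_adjacency(MONTAGE_11)
CENTRAL = {MONTAGE_11.index(c) for c in ("C3", "Cz", "C4")}


class TestAdjacency:
    def test_montage_structure(self):
        # triangulation neighborhoods: vertex at the center, no C3-C4 link
        assert {"Fz", "C3", "C4", "Pz"} <= set(ADJ.neighbors("Cz"))
        assert "C4" not in ADJ.neighbors("C3")
        assert "O1" not in ADJ.neighbors("F3")
        assert ADJ.matrix.sum() % 2 == 0

    def test_roundtrip_csv(self, tmp_path):
        path = tmp_path / "adj.csv"
        ADJ.to_csv(path)
        back = Adjacency.read_csv(path, labels=MONTAGE_11)
        assert np.array_equal(back.matrix, ADJ.matrix)

    def test_asymmetric_rejected(self):
        m = np.zeros((3, 3), bool)
        m[0, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            Adjacency(("a", "b", "c"), m)

    def test_grid_adjacency_links(self):
        g = grid_adjacency(ADJ, 3).toarray()
        cz, fz = MONTAGE_11.index("Cz"), MONTAGE_11.index("Fz")
        assert g[cz * 3 + 0, cz * 3 + 1]          # consecutive bins
        assert not g[cz * 3 + 0, cz * 3 + 2]      # skip-bin not adjacent
        assert g[cz * 3 + 1, fz * 3 + 1]          # neighbor channel, same bin
        assert not g[cz * 3 + 1, fz * 3 + 2]      # no diagonal links


class TestClusterPermutationTest:
    def test_planted_central_shift_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal((20, 11))
            b = rng.standard_normal((20, 11))
            a[:, list(CENTRAL)] += 2.0
            res = cluster_permutation_test(a, b, ADJ, n_permutations=300,
                                           seed=seed, labels=MONTAGE_11)
            sig = res.significant()
            if sig and set(sig[0].members) <= CENTRAL and \
                    MONTAGE_11.index("Cz") in sig[0].members:
                hits += 1
        assert hits >= 9

    def test_subject_order_invariance_paired(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((12, 11))
        b = rng.standard_normal((12, 11)) - 0.8
        res1 = cluster_permutation_test(a, b, ADJ, paired=True,
                                        n_permutations=200, seed=3)
        perm = rng.permutation(12)
        res2 = cluster_permutation_test(a[perm], b[perm], ADJ, paired=True,
                                        n_permutations=200, seed=3)
        assert [(c.members, c.p) for c in res1.clusters] == \
               [(c.members, c.p) for c in res2.clusters]
        assert np.array_equal(res1.null_max_size, res2.null_max_size)

    def test_channel_order_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((15, 11)) + np.linspace(0, 1.5, 11)
        b = rng.standard_normal((15, 11))
        res1 = cluster_permutation_test(a, b, ADJ, n_permutations=200, seed=5)
        order = rng.permutation(11)
        adj2 = Adjacency(tuple(MONTAGE_11[i] for i in order),
                         ADJ.matrix[np.ix_(order, order)])
        res2 = cluster_permutation_test(a[:, order], b[:, order], adj2,
                                        n_permutations=200, seed=5)
        m1 = sorted(tuple(sorted(c.members)) for c in res1.clusters)
        m2 = sorted(tuple(sorted(int(order[i]) for i in c.members))
                    for c in res2.clusters)
        assert m1 == m2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((10, 11)) + 1
        b = rng.standard_normal((10, 11))
        r1 = cluster_permutation_test(a, b, ADJ, n_permutations=100, seed=7)
        r2 = cluster_permutation_test(a, b, ADJ, n_permutations=100, seed=7)
        assert [(c.members, c.p) for c in r1.clusters] == \
               [(c.members, c.p) for c in r2.clusters]

    def test_identical_data_yield_no_clusters(self):
        a = np.ones((6, 11))
        b = np.ones((6, 11))
        res = cluster_permutation_test(a, b, ADJ, n_permutations=50, seed=0)
        assert res.clusters == []

    def test_p_values_bounded_below(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((10, 11)) + 5
        b = rng.standard_normal((10, 11))
        res = cluster_permutation_test(a, b, ADJ, n_permutations=99, seed=9)
        assert all(c.p >= 1 / 100 for c in res.clusters)

    def test_isolated_channel_forms_singleton_cluster(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((20, 11))
        b = rng.standard_normal((20, 11))
        o2 = MONTAGE_11.index("O2")
        a[:, o2] += 3.0
        res = cluster_permutation_test(a, b, ADJ, n_permutations=100, seed=11)
        assert any(c.members == (o2,) for c in res.clusters)


class TestClusterCorrectedSpearman:
    def test_rho_to_t_closed_form(self):
        assert _rho_to_t(0.5, 17) == pytest.approx(np.sqrt(5), abs=1e-12)

    def test_perfect_rho_capped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="capping"):
            t = _rho_to_t(np.array([1.0]), 10)
        assert t[0] > 1e5

    def test_planted_association_found(self):
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            y = rng.standard_normal(40)
            x = rng.standard_normal((40, 11))
            x[:, list(CENTRAL)] += 0.9 * y[:, None]
            res = cluster_corrected_spearman(x, y, ADJ, n_permutations=300,
                                             seed=seed, labels=MONTAGE_11)
            sig = res.significant()
            if sig and set(sig[0].members) & CENTRAL:
                hits += 1
        assert hits >= 7

    def test_effect_size_is_mean_rho(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal(30)
        x = rng.standard_normal((30, 11)) + 2.0 * y[:, None]
        res = cluster_corrected_spearman(x, y, ADJ, n_permutations=100, seed=13)
        c = res.clusters[0]
        manual = np.mean([spearmanr(x[:, i], y).statistic for i in c.members])
        assert c.effect_size == pytest.approx(manual, abs=1e-12)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(14)
        y = rng.standard_normal(25)
        x = rng.standard_normal((25, 11)) + y[:, None]
        r1 = cluster_corrected_spearman(x, y, ADJ, n_permutations=150, seed=15)
        perm = rng.permutation(25)
        r2 = cluster_corrected_spearman(x[perm], y[perm], ADJ,
                                        n_permutations=150, seed=15)
        assert [(c.members, c.p) for c in r1.clusters] == \
               [(c.members, c.p) for c in r2.clusters]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="5 subjects"):
            cluster_corrected_spearman(np.zeros((4, 11)), np.zeros(4), ADJ)


class TestPartialSpearman:
    def test_reduces_to_spearman_without_covariates(self):
        rng = np.random.default_rng(16)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        assert partial_spearman(x, y) == pytest.approx(
            spearmanr(x, y).statistic, abs=1e-12)

    def test_independent_covariate_changes_little(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(200)
        y = 0.5 * x + rng.standard_normal(200)
        z = rng.standard_normal(200)
        assert abs(partial_spearman(x, y, z) - partial_spearman(x, y)) < 0.05

    def test_full_removal_when_y_equals_covariate(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal(100)
        y = 0.7 * x + 0.3 * rng.standard_normal(100)
        assert abs(partial_spearman(x, y, covariates=y)) < 1e-8

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(19)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        z = rng.standard_normal(30)
        with pytest.raises(ValueError, match="collinear"):
            partial_spearman(x, y, covariates=np.column_stack([z, 2 * z]))

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(20)
        df = pd.DataFrame({"x": rng.standard_normal(60)})
        df["z"] = rng.standard_normal(60)
        df["y"] = 0.5 * df.x + 0.4 * df.z + rng.standard_normal(60)
        ours = partial_spearman(df.x, df.y, df.z)
        theirs = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                       method="spearman")["r"].iloc[0]
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestCohensD:
    def test_identical_groups_give_zero(self):
        a = np.random.default_rng(30).standard_normal((8, 5))
        assert cohens_d_cluster(a, a.copy(), [0, 1, 2]) == pytest.approx(0.0)

    def test_unit_shift_gives_unit_d(self):
        rng = np.random.default_rng(21)
        a = rng.standard_normal((200, 3)) + 1.0
        b = rng.standard_normal((200, 3))
        assert cohens_d_cluster(a, b, [0, 1, 2]) == pytest.approx(1.0, abs=0.1)

    def test_single_member_cluster(self):
        rng = np.random.default_rng(22)
        a = rng.standard_normal((50, 4))
        b = rng.standard_normal((50, 4)) - 0.5
        assert cohens_d_cluster(a, b, [2]) == pytest.approx(
            cohens_d(a, b)[2], abs=1e-12)

    def test_zero_sd_member_skipped_with_warning(self):
        a = np.column_stack([np.ones(10), np.arange(10.0)])
        b = np.column_stack([np.ones(10), np.arange(10.0) - 2])
        with pytest.warns(RuntimeWarning, match="zero pooled SD"):
            d = cohens_d_cluster(a, b, [0, 1])
        assert np.isfinite(d)
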