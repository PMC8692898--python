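"""Expression statistics: QC filtering, p-EMT scoring against brute-force
oracles, rank-sum comparisons, marker-gene selection and gated group tests."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from itertools import combinations
from scipy import stats

import serialstain as ss


def _adata(X, genes=None, labels=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    obs = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(X.shape[0])], name="cell"))
    if labels is not None:
        obs["group"] = labels
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


class TestQcFilter:
    def test_cell_boundary_at_min_genes(self):
        """399 expressed genes -> removed; 400 -> kept."""
        n_genes = 500
        X = np.zeros((3, n_genes))
        X[0, :399] = 1.0
        X[1, :400] = 1.0
        X[2, :] = 1.0
        out = ss.qc_filter(_adata(X), min_genes_per_cell=400, min_cells_per_gene=1)
        assert list(out.obs_names) == ["c1", "c2"]

    def test_gene_boundary_at_min_cells(self):
        """Expressed in 4 cells -> kept; in 3 -> removed."""
        X = np.zeros((10, 3))
        X[:4, 0] = 1.0  # 4 cells
        X[:3, 1] = 1.0  # 3 cells
        X[:, 2] = 1.0
        out = ss.qc_filter(_adata(X), min_genes_per_cell=1, min_cells_per_gene=4)
        assert list(out.var_names) == ["g0", "g2"]

    def test_toy_matrix_matches_hand_enumeration(self):
        """6x6 toy: cell c5 (2 expressed < 3) and genes g4, g5 (expressed in
        <2 surviving cells) fail by construction -> 5x4 survivor set."""
        X = np.array(
            [
                [5, 1, 2, 1, 0, 0],
                [1, 3, 1, 2, 1, 0],
                [2, 1, 4, 1, 0, 0],
                [1, 2, 1, 3, 0, 0],
                [3, 1, 2, 1, 0, 1],
                [1, 1, 0, 0, 0, 0],  # only 2 expressed genes
            ],
            dtype=float,
        )
        out = ss.qc_filter(_adata(X), min_genes_per_cell=3, min_cells_per_gene=2)
        assert out.shape == (5, 4)
        assert list(out.obs_names) == ["c0", "c1", "c2", "c3", "c4"]
        assert list(out.var_names) == ["g0", "g1", "g2", "g3"]

    def test_matches_scanpy_filters(self):
        """Cross-check the cells-then-genes pass against scanpy's filters."""
        sc = pytest.importorskip("scanpy")
        rng = np.random.default_rng(0)
        X = rng.poisson(0.3, size=(80, 120)).astype(float)
        ours = ss.qc_filter(_adata(X), min_genes_per_cell=20, min_cells_per_gene=4)
        ref = _adata(X)
        sc.pp.filter_cells(ref, min_genes=20)
        sc.pp.filter_genes(ref, min_cells=4)
        assert list(ours.obs_names) == list(ref.obs_names)
        assert list(ours.var_names) == list(ref.var_names)
        np.testing.assert_array_equal(ours.X, ref.X)

    def test_rerun_is_noop(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(0.5, size=(60, 100)).astype(float)
        once = ss.qc_filter(_adata(X), min_genes_per_cell=10, min_cells_per_gene=4)
        twice = ss.qc_filter(once, min_genes_per_cell=10, min_cells_per_gene=4)
        assert once.shape == twice.shape
        np.testing.assert_array_equal(once.X, twice.X)

    def test_all_cells_removed_raises(self):
        with pytest.raises(ValueError):
            ss.qc_filter(_adata(np.zeros((5, 10))), min_genes_per_cell=1)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            ss.qc_filter(_adata(-np.ones((5, 10))))


def _pemt_oracle(X, sig_idx):
    """Independent per-cell sort-and-rank oracle with average ties."""
    n_cells, n_genes = X.shape
    out = np.empty(n_cells)
    for i in range(n_cells):
        order = np.argsort(X[i], kind="stable")
        ranks = np.empty(n_genes)
        j = 0
        while j < n_genes:
            k = j
            while k + 1 < n_genes and X[i, order[k + 1]] == X[i, order[j]]:
                k += 1
            avg = (j + k) / 2.0 + 1.0  # 1-based average rank of the tie block
            for m in range(j, k + 1):
                ranks[order[m]] = avg
            j = k + 1
        out[i] = ranks[sig_idx].mean() / n_genes
    return out


class TestPemtScore:
    def test_all_ties_score(self):
        G = 10
        X = np.ones((1, G))
        score = ss.pemt_score(_adata(X), ["g0", "g3"])
        assert score.scores[0] == pytest.approx(0.5 + 1.0 / (2 * G))

    def test_top_gene_scores_one(self):
        X = np.arange(1.0, 7.0).reshape(1, 6)
        score = ss.pemt_score(_adata(X), ["g5"])
        assert score.scores[0] == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(7)
        X = rng.poisson(2.0, size=(50, 200)).astype(float)
        adata = _adata(X)
        sig = [f"g{j}" for j in range(0, 200, 10)]  # 20 genes
        score = ss.pemt_score(adata, sig)
        expected = _pemt_oracle(X, np.arange(0, 200, 10))
        np.testing.assert_array_equal(score.scores, expected)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), power=st.floats(0.2, 3.0))
    def test_invariant_under_monotone_transform(self, seed, power):
        rng = np.random.default_rng(seed)
        X = rng.gamma(2.0, 1.0, size=(8, 30))
        sig = ["g2", "g11", "g25"]
        s0 = ss.pemt_score(_adata(X), sig).scores
        s1 = ss.pemt_score(_adata(np.power(X, power) * 3.0 + 1.0), sig).scores
        np.testing.assert_allclose(s0, s1, atol=1e-12)

    def test_missing_signature_genes_counted(self):
        X = np.random.default_rng(0).poisson(2, (5, 10)).astype(float)
        score = ss.pemt_score(_adata(X), ["g1", "g2", "ABSENT"])
        assert score.n_signature_used == 2

    def test_no_signature_gene_raises(self):
        with pytest.raises(ValueError):
            ss.pemt_score(_adata(np.ones((3, 4))), ["NOPE"])

    def test_per_gene_orientation(self):
        """Alternative reading: rank cells within each gene."""
        X = np.array([[1.0, 5.0], [2.0, 1.0], [3.0, 2.0]])
        score = ss.pemt_score(_adata(X), ["g0"], orientation="per_gene")
        np.testing.assert_allclose(score.scores, [1 / 3, 2 / 3, 1.0])


class TestCompareScores:
    def test_identical_multisets_p_one(self):
        scores = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        groups = ["a", "a", "a", "b", "b", "b"]
        res = ss.compare_scores(scores, groups)
        assert res.p == pytest.approx(1.0)

    def test_small_example_matches_enumeration(self):
        """{1,2,3} vs {4,5,6}: U = 0 and p equals the exhaustive-permutation
        two-sided tail over all C(6,3)=20 assignments."""
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = ss.compare_scores(vals, ["x"] * 3 + ["y"] * 3)
        assert res.statistic == 0.0
        u_null = []
        for idx in combinations(range(6), 3):
            x = vals[list(idx)]
            u = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in np.delete(vals, list(idx)))
            u_null.append(u)
        u_null = np.asarray(u_null)
        mu = 4.5
        p_exact = np.mean(np.abs(u_null - mu) >= np.abs(0.0 - mu))
        assert res.p == pytest.approx(p_exact)

    def test_group_too_small_raises(self):
        with pytest.raises(ValueError):
            ss.compare_scores(np.arange(5.0), ["a", "a", "b", "b", "b"])

    def test_reproducible(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=200)
        groups = ["a"] * 100 + ["b"] * 100
        r1 = ss.compare_scores(scores, groups)
        r2 = ss.compare_scores(scores, groups)
        assert (r1.statistic, r1.p) == (r2.statistic, r2.p)


class TestFindMarkers:
    def _planted(self, seed=0):
        rng = np.random.default_rng(seed)
        n_t, n_r, n_genes = 50, 150, 60
        base = rng.lognormal(0.5, 0.3, n_genes)
        X = rng.poisson(base, size=(n_t + n_r, n_genes)).astype(float)
        clusters = np.array(["eCAF"] * n_t + ["other"] * n_r)
        X[:n_t, 0] = rng.poisson(base[0] * 10, n_t)  # true marker, x10
        X[:n_t, 1] = rng.poisson(base[1] * 1.5, n_t)  # below the fold rule
        return _adata(X), clusters

    def test_planted_marker_recovered_and_weak_excluded(self):
        adata, clusters = self._planted()
        table = ss.find_markers(adata, clusters, "eCAF")
        assert "g0" in set(table.gene)
        assert "g1" not in set(table.gene)

    def test_constant_gene_excluded(self):
        X = np.ones((20, 3))
        X[:10, 1] = 10.0
        table = ss.find_markers(_adata(X), ["a"] * 10 + ["b"] * 10, "a")
        assert "g0" not in set(table.gene)
        assert "g2" not in set(table.gene)

    def test_toy_hand_checked(self):
        """3 genes: g0 satisfies both rules, g1 fails the fold rule, g2 fails
        significance (identical distributions)."""
        n = 12
        target = np.array(["t"] * n + ["r"] * n)
        X = np.zeros((2 * n, 3))
        X[:n, 0] = 10.0
        X[n:, 0] = 1.0  # fold 10, clearly significant
        X[:n, 1] = 1.9
        X[n:, 1] = 1.0  # significant but fold < 2
        X[:, 2] = np.tile([1.0, 2.0], n)  # exchangeable
        table = ss.find_markers(_adata(X), target, "t")
        assert list(table.gene) == ["g0"]
        # Bonferroni over the 3 tested genes, asymptotic rank-sum
        from serialstain.expression import _rank_sum_test

        _, p_raw = _rank_sum_test(X[:n, 0], X[n:, 0])
        assert table.p_adj[0] == pytest.approx(min(p_raw * 3, 1.0))

    def test_invariant_to_gene_and_cell_order(self):
        adata, clusters = self._planted(seed=5)
        t1 = ss.find_markers(adata, clusters, "eCAF")
        rng = np.random.default_rng(0)
        gene_perm = rng.permutation(adata.n_vars)
        cell_perm = rng.permutation(adata.n_obs)
        shuffled = adata[cell_perm, gene_perm].copy()
        t2 = ss.find_markers(shuffled, clusters[cell_perm], "eCAF")
        assert set(t1.gene) == set(t2.gene)
        m1 = t1.set_index("gene").loc[sorted(t1.gene)]
        m2 = t2.set_index("gene").loc[sorted(t1.gene)]
        np.testing.assert_allclose(m1.fold_change, m2.fold_change)

    def test_single_cluster_raises(self):
        with pytest.raises(ValueError):
            ss.find_markers(_adata(np.ones((6, 3))), ["a"] * 6, "a")


class TestCompareFractions:
    def test_identical_groups_p_one(self):
        res = ss.compare_fractions([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        assert res.p == pytest.approx(1.0)
        # the rank-sum path itself gives p = 1 on exchangeable all-tied input
        from serialstain.expression import _rank_sum_test

        _, p = _rank_sum_test(np.array([0.2, 0.2, 0.2]), np.array([0.2, 0.2, 0.2]))
        assert p == 1.0

    def test_degenerate_paired_differences_fall_back(self):
        res = ss.compare_fractions([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], paired=True)
        assert res.method == "wilcoxon_signed_rank"
        assert res.normality_gate == "degenerate_differences"

    def test_normal_data_uses_t(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.5, 0.05, 12)
        b = rng.normal(0.6, 0.05, 12)
        res = ss.compare_fractions(a, b)
        assert res.method == "t_unpaired"
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.p == pytest.approx(ref.pvalue)

    def test_unequal_sd_routes_to_mann_whitney(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.5, 0.01, 15)
        b = rng.normal(0.5, 0.5, 15)
        res = ss.compare_fractions(a, b)
        assert res.method == "mann_whitney"

    def test_power_matches_analytic_t(self):
        """Normal groups, n=30, shift 0.75 SD: empirical rejection rate of the
        gated test within 5% of the closed-form two-sample t power."""
        n, delta = 30, 0.75
        n_sims = 400
        rng = np.random.default_rng(13)
        rejections = 0
        for _ in range(n_sims):
            a = rng.normal(0.0, 1.0, n)
            b = rng.normal(delta, 1.0, n)
            rejections += ss.compare_fractions(a, b).p < 0.05
        ncp = delta / np.sqrt(2.0 / n)
        df = 2 * n - 2
        tcrit = stats.t.ppf(0.975, df)
        power = 1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        assert abs(rejections / n_sims - power) <= 0.05

    def test_insufficient_n_raises(self):
        with pytest.raises(ValueError):
            ss.compare_fractions([1.0, 2.0], [1.0, 2.0, 3.0])
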