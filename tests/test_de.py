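"""Differential expression, pseudo-bulk, and cluster relationships."""

from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from v1atlas import preprocess
from v1atlas.de import (age_degs, cluster_correlation, cluster_tree,
                        find_markers, pseudobulk, pseudobulk_de,
                        rank_sum_test, size_factors, tree_to_newick,
                        wilcoxon_de)


def exact_ranksum_oracle(a, b):
    """Independent brute-force two-sided p: enumerate every rank assignment."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    mu = n1 * (len(pooled) + 1) / 2.0
    obs = ranks[:n1].sum()
    total = 0
    extreme = 0
    for comb in combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


class TestRankSum:
    def test_worked_example_exact(self):
        # A={1,2,3} vs B={4,5,6}: most extreme split, exact two-sided 0.1
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_matches_enumeration_oracle_small_samples(self, rng):
        for _ in range(40):
            n1 = int(rng.integers(2, 9))
            n2 = int(rng.integers(2, 9))
            a = rng.integers(0, 6, size=n1).astype(float)
            b = rng.integers(0, 6, size=n2).astype(float)
            _, p = rank_sum_test(a, b)
            assert p == pytest.approx(exact_ranksum_oracle(a, b), abs=1e-12)

    def test_large_sample_normal_approx_close_to_scipy(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=25)
        _, p = rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 use_continuity=False).pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            rank_sum_test([], [1.0])


def norm_from_counts(X, genes=None, **obs):
    X = np.asarray(X)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=pd.DataFrame(obs, index=[f"n{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=genes))
    return preprocess.lognormalize(adata)


class TestWilcoxonDE:
    def test_identical_groups_null(self, rng):
        X = rng.poisson(5, size=(40, 6))
        norm = norm_from_counts(np.vstack([X, X]))
        res = wilcoxon_de(norm, np.arange(40), np.arange(40, 80))
        assert np.allclose(res["log2fc"], 0.0, atol=1e-12)
        assert (res["pval"] >= 0.99).all()

    def test_boundary_log2fc_not_significant(self):
        # a gene with |log2FC| exactly 0.25 fails the strict > rule even at
        # p ~ 0; engineered via expm1 means 1.0 vs ~0.6818 (ratio 2^0.25)
        a_val = np.log1p(1.0)
        b_val = np.log1p(2.0 / 2 ** 0.25 - 1.0)
        A = np.full(30, a_val)
        B = np.full(30, b_val)
        lfc = np.log2((np.expm1(A).mean() + 1) / (np.expm1(B).mean() + 1))
        assert lfc == pytest.approx(0.25, abs=1e-12)
        adata = ad.AnnData(X=np.concatenate([A, B])[:, None],
                           var=pd.DataFrame(index=["g0"]))
        res = wilcoxon_de(adata, np.arange(30), np.arange(30, 60))
        assert not res["significant"].iloc[0]

    def test_bonferroni_monotone_and_capped(self, rng):
        X = rng.poisson(4, size=(60, 30))
        norm = norm_from_counts(X)
        res = wilcoxon_de(norm, np.arange(30), np.arange(30, 60))
        assert (res["padj"] >= res["pval"] - 1e-15).all()
        assert (res["padj"] <= 1.0).all()

    def test_missing_gene_raises(self, rng):
        norm = norm_from_counts(rng.poisson(4, size=(10, 3)))
        with pytest.raises(ValueError, match="absent"):
            wilcoxon_de(norm, [0, 1], [2, 3], genes=["nope"])


class TestFindMarkers:
    def _clustered(self, rng):
        base = rng.poisson(4, size=(90, 20))
        base[:30, 0] += 40   # marker of cluster 0
        base[30:60, 1] += 40  # marker of cluster 1
        norm = norm_from_counts(base)
        return norm, np.repeat([0, 1, 2], 30)

    def test_exclusive_gene_is_top_marker(self, rng):
        norm, cl = self._clustered(rng)
        markers = find_markers(norm, cl)
        assert markers[0].index[0] == "g0"
        assert markers[1].index[0] == "g1"

    def test_pairwise_antisymmetric_log2fc(self, rng):
        norm, cl = self._clustered(rng)
        ab = wilcoxon_de(norm, cl == 0, cl == 1)
        ba = wilcoxon_de(norm, cl == 1, cl == 0)
        assert np.allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)

    def test_planted_markers_recovered(self, atlas_norm):
        # each planted population's marker gene must surface in its
        # cluster's top-10 one-vs-rest list
        norm, truth = atlas_norm
        clusters = norm.obs["cluster"].to_numpy()
        tk = truth.nuclei.loc[norm.obs_names]
        marker_of = {"V1_Foxp2": "Foxp2", "V1_Sp8": "Sp8",
                     "V1_Pou6f2": "Pou6f2", "V1_Rnf220": "Rnf220",
                     "V1_Nr5a2": "Nr5a2"}
        genes = list({g for g in marker_of.values()} | set(norm.var_names[:200]))
        markers = find_markers(norm, clusters, genes=genes)
        found = 0
        for pop, gene in marker_of.items():
            mask = (tk["population"] == pop).to_numpy()
            c = pd.Series(clusters[mask]).mode()[0]
            if gene in markers[c].index[:10]:
                found += 1
        assert found >= len(marker_of) - 1


class TestAgeDEGs:
    def test_monotone_gene_enriched_in_old_not_young(self, rng):
        n = 120
        ages = np.repeat(["P0", "P14", "P28", "P56"], n // 4)
        X = rng.poisson(4, size=(n, 10))
        bump = {"P0": 0, "P14": 4, "P28": 8, "P56": 12}
        X[:, 3] += np.array([bump[a] for a in ages])
        norm = norm_from_counts(X, age=ages)
        res = age_degs(norm)
        assert "g3" in res["P28+P56"].index
        assert "g3" not in res["P0"].index

    def test_null_data_mostly_empty(self, rng):
        n = 120
        ages = np.repeat(["P0", "P14", "P28", "P56"], n // 4)
        X = rng.poisson(4, size=(n, 40))
        norm = norm_from_counts(X, age=ages)
        res = age_degs(norm)
        assert len(res["P0"]) + len(res["P28+P56"]) <= 2

    def test_planted_age_genes_recovered(self, rng):
        # 50 planted P0-specific genes among 400; the bump must survive
        # depth normalization, so most of the transcriptome stays untouched
        n = 160
        ages = np.repeat(["P0", "P14", "P28", "P56"], n // 4)
        X = rng.poisson(3, size=(n, 400))
        planted = list(range(50))
        mask = np.asarray(ages) == "P0"
        X[np.ix_(mask, planted)] += 8
        norm = norm_from_counts(X, age=ages)
        res = age_degs(norm)
        hits = sum(f"g{j}" in res["P0"].index for j in planted)
        assert hits >= 45


class TestPseudobulk:
    def test_single_nucleus_group_identity(self, rng):
        X = rng.poisson(5, size=(3, 8))
        adata = ad.AnnData(X=X.astype(np.int64))
        agg = pseudobulk(adata, ["a", "b", "c"])
        assert np.array_equal(np.asarray(agg.X), X)

    def test_conservation_of_total_counts(self, atlas_small):
        adata, _ = atlas_small
        agg = pseudobulk(adata, "sample")
        assert agg.X.sum() == adata.X.sum()

    def test_hand_sums(self):
        X = np.array([[1, 2, 3], [4, 5, 6]])
        adata = ad.AnnData(X=X.astype(np.int64))
        agg = pseudobulk(adata, ["g", "g"])
        assert np.array_equal(np.asarray(agg.X), [[5, 7, 9]])

    def test_linearity_over_unions(self, rng):
        X = rng.poisson(5, size=(12, 6)).astype(np.int64)
        adata = ad.AnnData(X=X)
        fine = pseudobulk(adata, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        coarse = pseudobulk(adata, ["ab"] * 8 + ["c"] * 4)
        assert np.array_equal(np.asarray(fine.X[:2]).sum(axis=0),
                              np.asarray(coarse.X[0]))

    def test_empty_group_raises(self, rng):
        adata = ad.AnnData(X=rng.poisson(5, size=(2, 3)).astype(np.int64))
        with pytest.raises(ValueError, match="empty"):
            pseudobulk(adata[[]], [])


class TestPseudobulkDE:
    def _agg(self, rng, n_genes=120, fold=None, depth=(1, 1, 1, 1)):
        base = rng.poisson(200, size=n_genes).astype(float) + 10
        X = np.vstack([rng.poisson(base * d) for d in depth]).astype(float)
        if fold is not None:
            gene, f = fold
            X[2:, gene] = rng.poisson(base[gene] * f * np.asarray(depth)[2:])
        agg = ad.AnnData(X=X)
        agg.obs["condition"] = ["het", "het", "ko", "ko"]
        return agg

    def test_size_factors_recover_depth_ratio(self, rng):
        agg = self._agg(rng, depth=(1, 1, 2, 2))
        sf = size_factors(np.asarray(agg.X))
        assert sf[2] / sf[0] == pytest.approx(2.0, rel=0.05)

    def test_null_few_discoveries(self, rng):
        agg = self._agg(rng)
        res = pseudobulk_de(agg, "condition")
        assert (res["padj"] < 0.05).sum() <= max(2, 0.01 * len(res))

    def test_planted_fourfold_gene_recovered(self, rng):
        agg = self._agg(rng, fold=(5, 4.0))
        res = pseudobulk_de(agg, "condition")
        assert res["padj"].iloc[5] < 0.05
        assert res["log2fc"].iloc[5] == pytest.approx(2.0, abs=0.5)

    def test_single_replicate_raises(self, rng):
        agg = self._agg(rng)[[0, 2]].copy()
        with pytest.raises(ValueError, match="single replicate"):
            pseudobulk_de(agg, "condition")

    def test_against_independent_deseq2_implementation(self, rng):
        # cross-check the minimal NB-Wald contract against pydeseq2 on the
        # same table: strong effects must agree in sign and significance
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        agg = self._agg(rng, fold=(5, 4.0))
        res = pseudobulk_de(agg, "condition")
        counts = pd.DataFrame(np.asarray(agg.X, dtype=int),
                              columns=[f"g{i}" for i in range(agg.n_vars)])
        meta = pd.DataFrame({"condition": agg.obs["condition"].to_numpy()})
        import logging
        logging.getLogger().setLevel(logging.ERROR)
        dds = DeseqDataSet(counts=counts, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "ko", "het"], quiet=True)
        ds.summary()
        ref = ds.results_df
        assert np.sign(ref["log2FoldChange"].iloc[5]) == \
            np.sign(res["log2fc"].iloc[5])
        assert ref["padj"].iloc[5] < 0.05 and res["padj"].iloc[5] < 0.05
        assert res["log2fc"].iloc[5] == pytest.approx(
            ref["log2FoldChange"].iloc[5], abs=0.3)


class TestClusterRelationships:
    def test_duplicate_profiles_merge_first_with_corr_one(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]],
            index=["a", "b", "c"])
        Z = cluster_tree(profiles)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == 0.0
        with np.errstate(invalid="ignore"):
            corr = cluster_correlation(profiles)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_correlation_symmetric_unit_diagonal_psd(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(5, 30)))
        corr = cluster_correlation(profiles)
        M = corr.to_numpy()
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)
        assert np.linalg.eigvalsh(M).min() >= -1e-10

    def test_merge_order_matches_hand_agglomeration(self):
        # 1-D profiles at 0, 1, 10: (0,1) merge at distance 1; the average
        # linkage to the third is (10 + 9) / 2 = 9.5
        profiles = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        Z = cluster_tree(profiles)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(9.5)

    def test_newick_roundtrip_leaves(self):
        profiles = pd.DataFrame(np.arange(8.0).reshape(4, 2),
                                index=["c0", "c1", "c2", "c3"])
        nwk = tree_to_newick(cluster_tree(profiles), profiles.index)
        assert nwk.endswith(";")
        import io as _io
        from Bio import Phylo
        tree = Phylo.read(_io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == \
            ["c0", "c1", "c2", "c3"]
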