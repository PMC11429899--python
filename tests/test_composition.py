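"""iLISI, genotype ratios, reference choice, and the DM model."""

import numpy as np
import pandas as pd
import pytest

from v1atlas.composition import (choose_reference, compute_ilisi, dm_test,
                                 normalized_genotype_ratio)


class TestILISI:
    def test_single_group_scores_one(self, rng):
        coords = rng.normal(size=(120, 2))
        scores = compute_ilisi(coords, np.zeros(120, dtype=int))
        assert np.allclose(scores, 1.0)

    def test_bounded_by_group_count(self, rng):
        coords = rng.normal(size=(400, 2))
        labels = rng.integers(0, 4, size=400)
        scores = compute_ilisi(coords, labels)
        assert scores.min() >= 1.0
        assert scores.max() <= 4.0

    def test_interleaved_lattice_approaches_group_count(self):
        # a fully interleaved 4-group lattice: every neighborhood contains
        # all groups in equal measure, so the median score approaches 4
        side = 40
        xs, ys = np.meshgrid(np.arange(side), np.arange(side))
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        labels = (xs.ravel() % 2) * 2 + (ys.ravel() % 2)
        scores = compute_ilisi(coords, labels)
        assert np.median(scores) > 3.5

    def test_separated_groups_score_low(self, rng):
        a = rng.normal(size=(100, 2))
        b = rng.normal(size=(100, 2)) + 50.0
        scores = compute_ilisi(np.vstack([a, b]), [0] * 100 + [1] * 100)
        assert np.median(scores) < 1.2

    def test_few_neighbors_shrinks_perplexity(self, rng):
        coords = rng.normal(size=(20, 2))
        with pytest.warns(UserWarning, match="shrinking perplexity"):
            scores = compute_ilisi(coords, [0, 1] * 10, perplexity=30)
        assert np.all((scores >= 1) & (scores <= 2))


class TestGenotypeRatio:
    def _comp(self, het, ko):
        return pd.DataFrame({"Het1": het, "KO1": ko},
                            index=range(len(het)))

    def test_identical_compositions_ratio_one(self):
        comp = self._comp([10, 20, 30], [10, 20, 30])
        geno = pd.Series({"Het1": "Het", "KO1": "KO"})
        ratios = normalized_genotype_ratio(comp, geno, numerator="Het")
        assert np.allclose(ratios.to_numpy(), 1.0)

    def test_hand_ratio(self):
        # cluster 0: Het 10/100 vs KO 5/100 -> ratio 2
        comp = self._comp([10, 90], [5, 95])
        geno = pd.Series({"Het1": "Het", "KO1": "KO"})
        ratios = normalized_genotype_ratio(comp, geno, numerator="Het")
        assert ratios.iloc[0, 0] == pytest.approx(2.0)

    def test_swapping_genotypes_inverts(self):
        comp = self._comp([10, 90], [5, 95])
        geno = pd.Series({"Het1": "Het", "KO1": "KO"})
        r1 = normalized_genotype_ratio(comp, geno, numerator="Het")
        r2 = normalized_genotype_ratio(comp, geno, numerator="KO")
        assert np.allclose(r1.to_numpy(), 1.0 / r2.to_numpy())

    def test_zero_denominator_is_inf(self):
        comp = self._comp([10, 90], [0, 100])
        geno = pd.Series({"Het1": "Het", "KO1": "KO"})
        ratios = normalized_genotype_ratio(comp, geno, numerator="Het")
        assert np.isinf(ratios.iloc[0, 0])

    def test_scale_invariance(self):
        comp = self._comp([10, 90], [5, 95])
        geno = pd.Series({"Het1": "Het", "KO1": "KO"})
        r1 = normalized_genotype_ratio(comp, geno, numerator="Het")
        comp2 = comp.copy()
        comp2["KO1"] *= 7
        r2 = normalized_genotype_ratio(comp2, geno, numerator="Het")
        assert np.allclose(r1.to_numpy(), r2.to_numpy())


class TestChooseReference:
    def _geno(self, cols):
        return pd.Series({c: ("Het" if c.startswith("H") else "KO")
                          for c in cols})

    def test_stable_abundant_cluster_chosen(self):
        comp = pd.DataFrame({
            "H1": [100, 100, 5], "H2": [110, 95, 6],
            "K1": [100, 60, 5], "K2": [105, 55, 6]},
            index=[0, 1, 2])
        ref = choose_reference(comp, self._geno(comp.columns))
        assert ref == 0  # abundant, unchanged between genotypes

    def test_all_identical_lowest_id(self):
        comp = pd.DataFrame({"H1": [50, 50], "H2": [50, 50],
                             "K1": [50, 50], "K2": [50, 50]}, index=[3, 7])
        assert choose_reference(comp, self._geno(comp.columns)) == 3

    def test_matches_bruteforce_ranking(self):
        comp = pd.DataFrame({
            "H1": [40, 80, 30], "H2": [42, 85, 28],
            "K1": [41, 70, 33], "K2": [39, 75, 31]},
            index=["a", "b", "c"])
        geno = self._geno(comp.columns)
        # brute force: filter to >= median abundance, rank by (|change|,
        # dispersion, id)
        rel = comp / comp.sum(axis=0)
        ab = rel.mean(axis=1)
        elig = [c for c in comp.index if ab[c] >= ab.median()]
        het = rel[["H1", "H2"]].mean(axis=1)
        ko = rel[["K1", "K2"]].mean(axis=1)
        key = {c: (abs(het[c] - ko[c]), rel.loc[c].std(ddof=1), c)
               for c in elig}
        expected = min(elig, key=lambda c: key[c])
        assert choose_reference(comp, geno) == expected


class TestDMTest:
    def _sample_comp(self, rng, n_per_sample, probs_het, probs_ko):
        cols = {}
        for s, p in (("HetR1", probs_het), ("HetR2", probs_het),
                     ("KoR1", probs_ko), ("KoR2", probs_ko)):
            cols[s] = rng.multinomial(n_per_sample, p)
        return pd.DataFrame(cols)

    @pytest.fixture(scope="class")
    def depletion_fit(self):
        rng = np.random.default_rng(2024)
        p = np.array([0.40, 0.20, 0.12, 0.05, 0.15, 0.08])
        p_ko = p.copy()
        p_ko[5] /= 3.0
        p_ko /= p_ko.sum()
        comp = self._sample_comp(rng, 2000, p, p_ko)
        geno = pd.Series({"HetR1": "Het", "HetR2": "Het",
                          "KoR1": "KO", "KoR2": "KO"})
        fit = dm_test(comp, geno, reference_cluster=0, fdr=0.05,
                      n_chains=4, n_draws=1500, n_burn=800, seed=9)
        return fit

    def test_depleted_cluster_is_only_credible_effect(self, depletion_fit):
        assert depletion_fit.credible_clusters() == [5]

    def test_effect_ci_covers_planted_log2fc(self, depletion_fit):
        row = depletion_fit.table.loc[5]
        planted = -np.log2(3.0)
        assert row["ci_low_log2"] <= planted <= row["ci_high_log2"]
        assert row["effect_log2"] < -1.0

    def test_reference_effect_fixed_zero(self, depletion_fit):
        row = depletion_fit.table.loc[0]
        assert row["effect_log2"] == 0.0
        assert row["inclusion_prob"] == 0.0
        assert not row["credible"]

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        p = np.array([0.5, 0.3, 0.2])
        comp = self._sample_comp(rng, 500, p, p)
        geno = pd.Series({"HetR1": "Het", "HetR2": "Het",
                          "KoR1": "KO", "KoR2": "KO"})
        kw = dict(reference_cluster=0, n_chains=2, n_draws=300, n_burn=200,
                  seed=17, check_convergence=False)
        f1 = dm_test(comp, geno, **kw)
        f2 = dm_test(comp, geno, **kw)
        pd.testing.assert_frame_equal(f1.table, f2.table)

    def test_null_rarely_credible(self):
        # a handful of null datasets; the full calibration (100 reps) runs
        # in the acceptance suite
        rng = np.random.default_rng(31)
        p = np.array([0.40, 0.20, 0.12, 0.05, 0.15, 0.08])
        geno = pd.Series({"HetR1": "Het", "HetR2": "Het",
                          "KoR1": "KO", "KoR2": "KO"})
        hits = 0
        for _ in range(10):
            comp = self._sample_comp(rng, 2000, p, p)
            fit = dm_test(comp, geno, reference_cluster=0, n_chains=2,
                          n_draws=400, n_burn=300, seed=int(rng.integers(2**31)),
                          check_convergence=False)
            hits += len(fit.credible_clusters()) > 0
        assert hits <= 1
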