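"""Pseudo-bulk partitioning, size factors, NB Wald, ranking, PCA, ORA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kaede_dcflow.pseudobulk import (
    PseudobulkDesign,
    bootstrap_rank,
    hypergeom_ora,
    nb_wald,
    partition_pseudoreps,
    pseudobulk_pca,
    size_factors_median_ratios,
    top_loading_genes,
)


class TestPartition:
    def test_count_conservation_and_disjointness(self, rng):
        counts = rng.integers(0, 20, size=(9, 30))
        pb = partition_pseudoreps(counts, 3, rng=0)
        assert pb.shape == (30, 3)
        np.testing.assert_array_equal(pb.sum(axis=1), counts.sum(axis=0))

    def test_near_equal_sizes_ten_cells(self):
        counts = np.ones((10, 1))
        pb = partition_pseudoreps(counts, 3, rng=1)
        assert sorted(pb.ravel().astype(int).tolist()) == [3, 3, 4]

    def test_same_seed_identical(self, rng):
        counts = rng.integers(0, 5, size=(12, 8))
        a = partition_pseudoreps(counts, 4, rng=5)
        b = partition_pseudoreps(counts, 4, rng=5)
        np.testing.assert_array_equal(a, b)

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            partition_pseudoreps(np.ones((2, 3)), 3, rng=0)


class TestSizeFactors:
    def test_proportional_columns_recover_constants(self, rng):
        profile = rng.lognormal(1, 1, size=200)
        c = np.array([1.0, 2.0, 4.0])
        k = np.outer(profile, c)
        s = size_factors_median_ratios(k)
        np.testing.assert_allclose(s / s[0], c, rtol=1e-10)

    def test_identical_columns_unit_factors(self):
        k = np.tile([[4.0], [2.0], [9.0]], (1, 4))
        np.testing.assert_allclose(size_factors_median_ratios(k), 1.0)

    def test_hand_computed_toy(self):
        k = np.array([[2.0, 4, 8], [1, 2, 4], [4, 8, 16]])
        s = size_factors_median_ratios(k)
        np.testing.assert_allclose(s / s[0], [1, 2, 4], rtol=1e-12)

    def test_gene_order_invariance_and_scaling(self, rng):
        k = rng.integers(1, 50, size=(40, 4)).astype(float)
        s = size_factors_median_ratios(k)
        perm = rng.permutation(40)
        np.testing.assert_allclose(size_factors_median_ratios(k[perm]), s)
        np.testing.assert_allclose(size_factors_median_ratios(3 * k), s)

    def test_no_reference_gene(self):
        k = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            size_factors_median_ratios(k)


GROUPS = np.array(["A", "A", "B", "B"])


class TestNBWald:
    def test_identical_group_means_null(self):
        pb = np.array([[10.0, 10, 10, 10]])
        res = nb_wald(pb, np.ones(4), GROUPS)
        assert res["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert res["pval"].iloc[0] == pytest.approx(1.0)

    def test_toy_matches_poisson_glm_oracle(self):
        """Counts (10,10 | 20,20): zero within-group variance floors the
        dispersion, so the fit is the Poisson GLM; statistic agrees with the
        independent statsmodels fit within 1e-4."""
        import statsmodels.api as sm

        pb = np.array([[10.0, 10, 20, 20]])
        res = nb_wald(pb, np.ones(4), GROUPS, contrast=("B", "A"))
        assert res["log2fc"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        x = sm.add_constant(np.array([0.0, 0, 1, 1]))
        fit = sm.GLM(pb[0], x, family=sm.families.Poisson()).fit()
        oracle_z = fit.params[1] / fit.bse[1]
        assert res["stat"].iloc[0] == pytest.approx(oracle_z, abs=1e-4)

    def test_poisson_limit_pvalues_match_oracle(self):
        """On the floored-dispersion toy the fit is a Poisson GLM: the
        statistic matches the statsmodels Wald z and the p-value matches the
        oracle z mapped through the same small-sample t reference, within
        1e-3."""
        import statsmodels.api as sm

        pb = np.array([[10.0, 10, 20, 20], [7, 9, 8, 8]])
        res = nb_wald(pb, np.ones(4), GROUPS, contrast=("B", "A"))
        x = sm.add_constant(np.array([0.0, 0, 1, 1]))
        fit = sm.GLM(pb[0], x, family=sm.families.Poisson()).fit()
        z = fit.params[1] / fit.bse[1]
        assert res["stat"].iloc[0] == pytest.approx(z, abs=1e-3)
        p_oracle = 2 * stats.t.sf(abs(z), 2)
        assert res["pval"].iloc[0] == pytest.approx(p_oracle, abs=1e-3)

    def test_sign_antisymmetry_exact(self, rng):
        pb = rng.poisson(30, size=(50, 4)).astype(float)
        sf = size_factors_median_ratios(pb + 1)
        fwd = nb_wald(pb, sf, GROUPS, contrast=("B", "A"))
        rev = nb_wald(pb, sf, GROUPS, contrast=("A", "B"))
        np.testing.assert_array_equal(fwd["stat"].to_numpy(), -rev["stat"].to_numpy())
        np.testing.assert_array_equal(fwd["log2fc"].to_numpy(), -rev["log2fc"].to_numpy())

    def test_null_calibration(self, rng):
        """No-DE NB counts at 3 pseudo-reps/group: rejection rate at 0.05
        within [0.03, 0.08]."""
        G = 2000
        mu = rng.lognormal(4, 1, G)
        alpha = rng.uniform(0.05, 0.3, G)
        k = rng.poisson(rng.gamma(1 / alpha[:, None], (mu * alpha)[:, None], (G, 6)))
        sf = size_factors_median_ratios(k)
        res = nb_wald(k, sf, np.array(["A"] * 3 + ["B"] * 3))
        rate = (res["pval"] < 0.05).mean()
        assert 0.03 <= rate <= 0.08

    def test_all_zero_group_gets_pseudocount(self):
        pb = np.array([[0.0, 0, 5, 7], [3, 4, 5, 6]])
        res = nb_wald(pb, np.ones(4), GROUPS)
        assert np.isfinite(res["log2fc"]).all()


class TestBootstrapRank:
    def test_b1_equals_single_nb_wald(self, s23_adata):
        design = PseudobulkDesign(n_boot=1, seed=3)
        ranked, stats_mat = bootstrap_rank(
            s23_adata, "state", ("S2_DC2", "S3_DC3"), design, return_stats=True
        )
        assert stats_mat.shape[1] == 1
        m = ranked.set_index("gene")["score"]
        order = np.argsort(-m.to_numpy(), kind="stable")
        assert (np.diff(m.to_numpy()[order]) <= 0).all()

    def test_rank_metric_stability_across_seeds(self, ranked_s23, s23_adata):
        other = bootstrap_rank(
            s23_adata, "state", ("S2_DC2", "S3_DC3"), PseudobulkDesign(seed=99)
        )
        a = ranked_s23.set_index("gene")["score"]
        b = other.set_index("gene")["score"]
        rho = stats.spearmanr(a, b.loc[a.index])[0]
        assert rho >= 0.95

    def test_planted_gene_recovery_auc(self, ranked_s23, default_program):
        from sklearn.metrics import roc_auc_score

        m = ranked_s23.set_index("gene")["score"]
        planted = default_program.signatures["dc2_marker"]
        nulls = [g for g in default_program.gene_names if g.startswith("NULL")]
        y = [1] * len(planted) + [0] * len(nulls)
        x = np.concatenate([m.loc[planted], m.loc[nulls]])
        assert roc_auc_score(y, x) >= 0.9

    def test_deterministic_given_seed(self, s23_adata):
        d = PseudobulkDesign(n_boot=2, seed=42)
        a = bootstrap_rank(s23_adata, "state", ("S2_DC2", "S3_DC3"), d)
        b = bootstrap_rank(s23_adata, "state", ("S2_DC2", "S3_DC3"), d)
        pd.testing.assert_frame_equal(a, b)


class TestPCA:
    def test_loadings_orthonormal(self, rng):
        pb = rng.poisson(20, size=(100, 8)).astype(float)
        _, loadings, _ = pseudobulk_pca(pb, np.ones(8), n_components=5)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(5), atol=1e-8)

    def test_block_difference_dominates_pc1(self, rng):
        pb = rng.poisson(50, size=(200, 6)).astype(float)
        pb[:50, 3:] *= 8  # 50-gene block separating the two sample groups
        comps, loadings, _ = pseudobulk_pca(pb, np.ones(6), n_components=2)
        top = top_loading_genes(loadings, [f"g{i}" for i in range(200)], 0, 50)
        assert len(set(top) & {f"g{i}" for i in range(50)}) >= 45

    def test_truncation_warns(self, rng):
        pb = rng.poisson(10, size=(30, 3)).astype(float)
        with pytest.warns(UserWarning, match="truncated"):
            _, loadings, _ = pseudobulk_pca(pb, np.ones(3), n_components=10)
        assert loadings.shape[1] == 2

    def test_duplicate_samples_degenerate_axis(self):
        pb = np.tile([[10.0], [20], [5]], (1, 4))
        _, _, var = pseudobulk_pca(pb, np.ones(4), n_components=2)
        assert var[0] == pytest.approx(0.0, abs=1e-12) or np.isnan(var[0])


class TestORA:
    def test_full_overlap_combinatoric(self):
        universe = [f"g{i}" for i in range(10)]
        res = hypergeom_ora(universe[:5], {"s": universe[:5]}, universe)
        assert res["pval"].iloc[0] == pytest.approx(1 / 252)

    def test_zero_draw(self):
        universe = [f"g{i}" for i in range(10)]
        res = hypergeom_ora([], {"s": universe[:3]}, universe)
        assert res["pval"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        universe = [f"g{i}" for i in range(10)]
        gene_set = set(universe[:5])
        draw = universe[2:7]
        obs = len(gene_set & set(draw))
        count = sum(
            1
            for combo in itertools.combinations(universe, 5)
            if len(gene_set & set(combo)) >= obs
        )
        res = hypergeom_ora(draw, {"s": list(gene_set)}, universe)
        assert res["pval"].iloc[0] == pytest.approx(count / 252)

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            hypergeom_ora(["a"], {"s": ["a"]}, [])
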