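"""QC, normalization, signature scoring, Wilcoxon DE, composition, transfer."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from kaede_dcflow.sc_core import (
    GeneSignature,
    extract_state_signature,
    green_count_ratio,
    kaede_composition,
    label_transfer,
    lognormalize,
    qc_filter,
    score_signature,
    wilcoxon_de,
)


def _adata(counts, genes=None, obs=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    a = ad.AnnData(
        X=sparse.csr_matrix(counts.astype(float)),
        var=pd.DataFrame(index=genes),
        obs=obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])]),
    )
    return a


class TestQC:
    def _mk(self, detected_per_cell, n_genes=1200, mito=0.01):
        rows = []
        for d in detected_per_cell:
            row = np.zeros(n_genes)
            row[:d] = 1
            rows.append(row)
        a = _adata(np.array(rows))
        a.obs["mito_fraction"] = mito
        return a

    def test_boundary_cells_retained_strict_rule(self):
        a = self._mk([999, 1000, 1100, 1200], n_genes=1200)
        out = qc_filter(a, min_genes=1000, max_genes=6000, min_cells_per_gene=1)
        # 999 detected genes -> removed; 1000 retained (strict < / > reading)
        assert out.n_obs == 3

    def test_mito_cutoff_removes_at_threshold(self):
        a = self._mk([1100, 1100, 1100], n_genes=1200)
        a.obs["mito_fraction"] = [0.074, 0.075, 0.2]
        out = qc_filter(a, min_genes=1000, max_genes=6000, min_cells_per_gene=1)
        assert out.n_obs == 1  # only the 0.074 cell survives

    def test_gene_detected_in_two_cells_removed(self):
        counts = np.ones((5, 6))
        counts[2:, 5] = 0  # gene 5 detected in 2 cells only
        a = _adata(counts)
        a.obs["mito_fraction"] = 0.0
        out = qc_filter(a, min_genes=1, max_genes=10, min_cells_per_gene=3)
        assert "g5" not in out.var_names

    def test_idempotent(self, s23_adata):
        once = qc_filter(s23_adata, min_genes=200, max_genes=1900)
        twice = qc_filter(once, min_genes=200, max_genes=1900)
        assert once.shape == twice.shape
        assert list(once.obs_names) == list(twice.obs_names)

    def test_empty_result_warns_not_raises(self, caplog):
        a = self._mk([10, 12], n_genes=100)
        out = qc_filter(a, min_genes=50, max_genes=90, min_cells_per_gene=1)
        assert out.n_obs == 0


class TestLognormalize:
    def test_toy_arithmetic(self):
        a = _adata([[1, 1, 2]])
        out = lognormalize(a, target_sum=1e4)
        np.testing.assert_allclose(
            out.X.toarray()[0], np.log1p([2500, 2500, 5000])
        )

    def test_uniform_counts_equal_entries(self):
        out = lognormalize(_adata([[3, 3, 3, 3]]))
        assert len(np.unique(out.X.toarray())) == 1

    def test_expm1_sum_recovers_target(self, rng):
        a = _adata(rng.integers(1, 20, size=(20, 50)))
        out = lognormalize(a, target_sum=1e4)
        sums = np.expm1(out.X.toarray()).sum(axis=1)
        np.testing.assert_allclose(sums, 1e4, rtol=1e-6)

    def test_all_zero_cell_named_in_error(self):
        a = _adata([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="c1"):
            lognormalize(a)


class TestScoreSignature:
    def test_constant_matrix_scores_zero(self):
        a = _adata(np.full((4, 30), 7.0))
        sig = GeneSignature("s", ["g0", "g1"])
        np.testing.assert_allclose(score_signature(a, sig, n_bins=1), 0.0)

    def test_toy_mean_difference(self):
        # 6 genes, 2 cells, one bin, control = full pool minus signature
        x = np.array([[1.0, 2, 3, 4, 5, 6], [2, 2, 2, 2, 2, 2]])
        a = _adata(x)
        sig = GeneSignature("s", ["g4", "g5"])
        scores = score_signature(a, sig, n_bins=1, ctrl_size=6, seed=0)
        expected = x[:, 4:].mean(axis=1) - x[:, :4].mean(axis=1)
        np.testing.assert_allclose(scores, expected)

    def test_missing_genes_error(self):
        a = _adata(np.ones((2, 3)))
        with pytest.raises(ValueError, match="zzz"):
            score_signature(a, GeneSignature("s", ["zzz"]))

    def test_matches_scanpy_when_controls_cover_pool(self, rng):
        """With controls covering the whole pool both implementations reduce
        to mean(signature) - mean(rest); the binning details drop out when
        the signature holds the top-mean gene."""
        sc = pytest.importorskip("scanpy")
        x = rng.lognormal(0, 1, size=(50, 40))
        x[:, 3] += 50.0  # make a signature gene the top-mean gene
        a = ad.AnnData(X=x.copy(), var=pd.DataFrame(index=[f"g{i}" for i in range(40)]))
        genes = ["g3", "g7", "g11"]
        sc.tl.score_genes(a, genes, ctrl_size=40, n_bins=2, score_name="sc")
        ours = score_signature(_adata(x), GeneSignature("s", genes), n_bins=1, ctrl_size=40)
        np.testing.assert_allclose(ours, a.obs["sc"].to_numpy(), atol=1e-10)

    def test_planted_signature_separates_states(self, s23_adata, default_program):
        norm = lognormalize(s23_adata)
        sig = GeneSignature("dc2", default_program.signatures["dc2_marker"])
        scores = score_signature(norm, sig, seed=0)
        s2 = scores[(norm.obs["state"] == "S2_DC2").to_numpy()]
        s3 = scores[(norm.obs["state"] == "S3_DC3").to_numpy()]
        assert s2.mean() > s3.mean() + 0.2


class TestWilcoxon:
    def test_identical_groups_null(self):
        x = np.tile([[1.0, 5.0, 2.0]], (6, 1))
        a = _adata(x)
        res = wilcoxon_de(a, np.arange(3), np.arange(3, 6))
        assert (res["pval"] > 0.99).all()

    def test_exact_3v3_enumeration(self):
        a = _adata(np.array([[1.0], [2], [3], [4], [5], [6]]))
        res = wilcoxon_de(a, np.arange(3), np.arange(3, 6))
        assert res["pval"].iloc[0] == pytest.approx(0.1)  # 2/20 assignments

    def test_overlap_rejected(self):
        a = _adata(np.ones((4, 2)))
        with pytest.raises(ValueError, match="overlap"):
            wilcoxon_de(a, [0, 1], [1, 2])

    def test_asymptotic_matches_scipy_per_gene(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.lognormal(0, 1, size=(30, 10))
        x[:, 3] = np.round(x[:, 3])  # force ties on one gene
        a = _adata(x)
        res = wilcoxon_de(a, np.arange(15), np.arange(15, 30))
        for j in [0, 3, 7]:
            ref = mannwhitneyu(
                x[:15, j], x[15:, j], alternative="two-sided", method="asymptotic"
            )
            assert res["pval"].iloc[j] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_bh_toy(self):
        padj = multipletests([0.01, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(padj, [0.02, 0.04])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20)
)
def test_bh_matches_direct_step_up(pvals):
    """BH as used throughout the package equals the direct step-up
    definition on random p-vectors."""
    p = np.asarray(pvals)
    ours = multipletests(p, method="fdr_bh")[1]
    m = len(p)
    order = np.argsort(p, kind="stable")
    direct = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        direct[i] = running
    np.testing.assert_allclose(ours, direct, atol=1e-12)


class TestSignatureExtraction:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "stat", "pval", "padj"])

    def test_strict_boundaries(self):
        de = self._de(
            [
                ["a", 2.0, 5.0, 1e-4, 0.05],  # padj == 0.05 -> excluded
                ["b", 1.0, 5.0, 1e-4, 0.01],  # lfc == 1 -> excluded
                ["c", 2.0, 5.0, 1e-4, 0.01],  # included
            ]
        )
        sig = extract_state_signature(de)
        assert sig.genes == ["c"]

    def test_all_null_gives_empty(self):
        de = self._de([["a", 0.1, 0.0, 0.9, 0.95]])
        assert extract_state_signature(de).genes == []

    def test_planted_de_recovery(self, s23_adata, default_program):
        """Planted DC2 markers (log2 effect 2) are recovered at >= 90% and
        null genes leak in at <= 5%."""
        norm = lognormalize(s23_adata)
        state = norm.obs["state"].to_numpy()
        de = wilcoxon_de(norm, state == "S2_DC2", state == "S3_DC3")
        sig = set(extract_state_signature(de).genes)
        planted = set(default_program.signatures["dc2_marker"])
        nulls = {g for g in default_program.gene_names if g.startswith("NULL")}
        assert len(sig & planted) / len(planted) >= 0.9
        assert len(sig & nulls) / len(nulls) <= 0.05


class TestComposition:
    def test_all_red(self):
        obs = pd.DataFrame({"kaede": ["red"] * 5, "cluster": list("aabbb")})
        comp = kaede_composition(obs)
        assert (comp["red_fraction"] == 1.0).all()

    def test_green_ratio_and_undefined(self):
        obs = pd.DataFrame(
            {
                "kaede": ["green"] + ["green"] * 100 + ["red"],
                "cluster": ["X"] + ["Y"] * 100 + ["Z"],
            }
        )
        comp = kaede_composition(obs)
        assert green_count_ratio(comp, "X", "Y") == pytest.approx(0.01)
        assert np.isnan(green_count_ratio(comp, "X", "Z"))

    def test_matches_occupancy_oracle(self, dwell_params):
        from kaede_dcflow.synthetic import expected_red_fraction, simulate_dwell

        reps = pd.concat(
            [simulate_dwell(dwell_params, seed=200 + s) for s in range(5)]
        )
        tum = reps[(reps["compartment"] == "tumour") & (reps["harvest_offset_h"] == 48)]
        comp = kaede_composition(tum, groupby="state").set_index("group")
        for s in ("S2_DC2", "S3_DC3"):
            n = comp.loc[s, ["n_green", "n_red"]].sum()
            f = comp.loc[s, "red_fraction"]
            se = np.sqrt(f * (1 - f) / n)
            oracle = expected_red_fraction(dwell_params, s, 48.0)
            assert abs(f - oracle) < 3 * max(se, 1e-3)

    def test_missing_labels_error(self):
        obs = pd.DataFrame({"kaede": ["red", None], "cluster": ["a", "a"]})
        with pytest.raises(ValueError):
            kaede_composition(obs)


class TestLabelTransfer:
    def test_identical_query_k1(self, rng):
        ref = rng.normal(size=(20, 10))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        pred, _ = label_transfer(ref, labels, ref[[3]], n_pcs=5, k=1)
        assert pred[0] == "a"

    def test_self_prediction_k1_exact(self, rng):
        ref = rng.normal(size=(30, 8))
        labels = np.array(["x", "y", "z"] * 10)
        pred, props = label_transfer(ref, labels, ref, n_pcs=5, k=1)
        assert (pred == labels).all()
        freqs = pd.Series(labels).value_counts(normalize=True)
        for _, row in props.iterrows():
            assert abs(row["fraction"] - freqs[row["label"]]) <= 1 / len(labels)

    def test_separated_clusters_accuracy(self, rng):
        centers = np.zeros((2, 20))
        centers[1, :] = 10.0  # 10x the within-cluster sd
        ref = np.vstack(
            [c + rng.normal(0, 1, size=(100, 20)) for c in centers]
        )
        labels = np.array(["a"] * 100 + ["b"] * 100)
        query = np.vstack(
            [c + rng.normal(0, 1, size=(50, 20)) for c in centers]
        )
        truth = np.array(["a"] * 50 + ["b"] * 50)
        pred, _ = label_transfer(ref, labels, query)
        assert (pred == truth).mean() >= 0.95

    def test_k_too_large(self, rng):
        ref = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="k exceeds"):
            label_transfer(ref, np.array(list("abcab")), ref, k=10)
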