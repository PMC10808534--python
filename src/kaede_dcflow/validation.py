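"""End-to-end validation computations.

Each function runs one part of the pipeline from scratch on freshly
generated synthetic data and returns the headline quantities (oracle
agreement, calibration rates, recovery metrics, co-localization statistics,
survival power, determinism).  They are shared by the acceptance test suite
and the ``scripts/acceptance.py`` reporting script; all randomness derives
from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from . import coloc, gsea, interactions, pseudobulk, sc_core, synthetic
from .cohort import SurvivalCohort, logrank, signature_survival
from .pipeline import load_config, run_end_to_end

OFFSETS = (5.0, 24.0, 48.0, 72.0)


def _seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=int(seed), spawn_key=(k,)).generate_state(1)[0] % (2**31))


# 1 -------------------------------------------------------------------------

def dwell_oracle_agreement(seed: int, n_reps: int = 200) -> dict:
    """Simulated per-state red fractions vs the matrix-exponential closed
    form, at every default harvest offset, over ``n_reps`` replicates."""
    params = synthetic.DwellModelParams()
    sims = {(s, d): [] for s in synthetic.STATES for d in OFFSETS}
    counts = []
    for r in range(n_reps):
        df = synthetic.simulate_dwell(params, seed=_seed(seed, r))
        tum = df[df["compartment"] == "tumour"]
        counts.append(len(tum[tum["harvest_offset_h"] == 48.0]))
        for d in OFFSETS:
            sub = tum[tum["harvest_offset_h"] == d]
            for s in synthetic.STATES:
                grp = sub[sub["state"] == s]
                if len(grp):
                    sims[(s, d)].append((grp["kaede"] == "red").mean())
    max_dev_se = 0.0
    for (s, d), vals in sims.items():
        vals = np.asarray(vals)
        se = max(vals.std(ddof=1) / np.sqrt(len(vals)), 1e-6)
        oracle = synthetic.expected_red_fraction(params, s, d)
        max_dev_se = max(max_dev_se, abs(vals.mean() - oracle) / se)
    s3 = np.mean(sims[("S3_DC3", 48.0)])
    return {
        "max_deviation_in_mc_se": float(max_dev_se),
        "red_fraction_s3_48h_simulated": float(s3),
        "red_fraction_s3_48h_oracle": float(
            synthetic.expected_red_fraction(params, "S3_DC3", 48.0)
        ),
        "min_tumour_cells_per_replicate": int(min(counts)),
    }


# 2 -------------------------------------------------------------------------

def size_factor_recovery(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    profile = rng.lognormal(1, 1, size=500)
    c = np.array([1.0, 2.0, 4.0, 0.5])
    s = pseudobulk.size_factors_median_ratios(np.outer(profile, c))
    err = float(np.max(np.abs(s / s[0] - c / c[0])))
    return {"size_factor_max_abs_error": err}


# 3 -------------------------------------------------------------------------

def nb_wald_calibration(seed: int, n_genes: int = 2000) -> dict:
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(4, 1, n_genes)
    alpha = rng.uniform(0.05, 0.3, n_genes)
    k = rng.poisson(rng.gamma(1 / alpha[:, None], (mu * alpha)[:, None], (n_genes, 6)))
    sf = pseudobulk.size_factors_median_ratios(k)
    groups = np.array(["A"] * 3 + ["B"] * 3)
    fwd = pseudobulk.nb_wald(k, sf, groups, contrast=("B", "A"))
    rev = pseudobulk.nb_wald(k, sf, groups, contrast=("A", "B"))
    antisym = bool(
        np.array_equal(fwd["stat"].to_numpy(), -rev["stat"].to_numpy())
    )
    return {
        "nb_wald_type1_rate": float((fwd["pval"] < 0.05).mean()),
        "nb_wald_sign_antisymmetry_exact": antisym,
    }


# 4 / 6 ---------------------------------------------------------------------

def _default_s23_dataset(seed: int):
    params = synthetic.DwellModelParams()
    cells = synthetic.simulate_dwell(params, seed=_seed(seed, 1000))
    cells = cells[
        (cells["compartment"] == "tumour")
        & (cells["state"].isin(["S2_DC2", "S3_DC3"]))
    ]
    program = synthetic.GeneProgram.default(seed=_seed(seed, 1001))
    adata = synthetic.sample_expression(cells, program, seed=_seed(seed, 1002))
    return adata, program


def bootstrap_rank_metrics(seed: int) -> dict:
    adata, program = _default_s23_dataset(seed)
    contrast = ("S2_DC2", "S3_DC3")
    r1 = pseudobulk.bootstrap_rank(
        adata, "state", contrast, pseudobulk.PseudobulkDesign(seed=_seed(seed, 1))
    )
    r2 = pseudobulk.bootstrap_rank(
        adata, "state", contrast, pseudobulk.PseudobulkDesign(seed=_seed(seed, 2))
    )
    a = r1.set_index("gene")["score"]
    b = r2.set_index("gene")["score"]
    rho = float(sps.spearmanr(a, b.loc[a.index])[0])
    planted = program.signatures["dc2_marker"]
    nulls = [g for g in program.gene_names if g.startswith("NULL")]
    y = [1] * len(planted) + [0] * len(nulls)
    x = np.concatenate([a.loc[planted], a.loc[nulls]])
    return {
        "rank_metric_spearman_across_seeds": rho,
        "planted_de_auc": float(roc_auc_score(y, x)),
        "_ranked": r1,
        "_program": program,
    }


def gsea_planted_hit_rate(seed: int, ranked=None, program=None, n_seeds: int = 20) -> dict:
    if ranked is None or program is None:
        out = bootstrap_rank_metrics(seed)
        ranked, program = out["_ranked"], out["_program"]
    sets = {k: list(v) for k, v in program.signatures.items()}
    hits = 0
    for j in range(n_seeds):
        res = gsea.prerank_gsea(
            ranked, sets, nperm=1000, seed=_seed(seed, 2000 + j)
        ).set_index("set")
        act = res.loc["activation"]
        hits += bool(act["es"] > 0 and act["padj"] < 0.05)
    return {"gsea_planted_activation_hit_rate": hits / n_seeds}


# 5 -------------------------------------------------------------------------

def gsea_exactness(seed: int) -> dict:
    genes = ["g1", "g2", "g3", "g4", "g5"]
    metrics = [5.0, 4.0, 3.0, 2.0, 1.0]
    es, run, _ = gsea.es_score(genes, metrics, {"g1", "g3"})
    # hand-enumerated running sum
    tot = 5.0 + 3.0
    hand = np.cumsum([5 / tot, -1 / 3, 3 / tot, -1 / 3, -1 / 3])
    es_err = float(abs(es - hand[np.argmax(np.abs(hand))]))

    ranked = pd.DataFrame(
        {"gene": [f"g{i}" for i in range(6)], "score": [3.0, 2.0, 1.0, -0.5, -1.0, -2.0]}
    )
    res = gsea.prerank_gsea(ranked, {"s": ["g1"]}, null="exhaustive", min_size=1)
    all_es = [
        gsea.es_score(ranked["gene"].tolist(), ranked["score"], {g})[0]
        for g in ranked["gene"]
    ]
    obs = all_es[1]
    same = [e for e in all_es if (e >= 0) == (obs >= 0)]
    manual = sum(abs(e) >= abs(obs) for e in same) / len(same)
    p_err = float(abs(res["pval"].iloc[0] - manual))
    return {"gsea_toy_es_error": es_err, "gsea_exhaustive_p_error": p_err}


# 7 -------------------------------------------------------------------------

def lr_calibration(seed: int, n_pairs: int = 1000) -> dict:
    rng = np.random.default_rng(_seed(seed, 1))
    import anndata as ad
    from scipy import sparse as sp

    x = rng.lognormal(0, 0.5, size=(400, 2 * n_pairs))
    adata = ad.AnnData(
        X=sp.csr_matrix(x),
        var=pd.DataFrame(index=[f"g{i}" for i in range(2 * n_pairs)]),
        obs=pd.DataFrame(
            {"cluster": ["A"] * 200 + ["B"] * 200},
            index=[f"c{i}" for i in range(400)],
        ),
    )
    pairs = [
        interactions.LRPair(f"p{j}", (f"g{2 * j}",), (f"g{2 * j + 1}",))
        for j in range(n_pairs)
    ]
    combos = [(p, "A", "B") for p in pairs]
    res = interactions.permutation_test(
        adata, "cluster", pairs, nperm=1000, seed=_seed(seed, 2), combos=combos
    )
    rate = float((res["pval"].dropna() < 0.05).mean())

    hits = 0
    n_seeds = 20
    for j in range(n_seeds):
        r = np.random.default_rng(_seed(seed, 100 + j))
        y = r.lognormal(0, 0.4, size=(300, 4))
        y[:100, 0] *= 4  # ligand 4-fold up in sender A
        y[100:200, 1] *= 4  # receptor 4-fold up in receiver B
        a2 = ad.AnnData(
            X=sp.csr_matrix(y),
            var=pd.DataFrame(index=["lig", "rec", "x1", "x2"]),
            obs=pd.DataFrame(
                {"cluster": ["A"] * 100 + ["B"] * 100 + ["C"] * 100},
                index=[f"c{i}" for i in range(300)],
            ),
        )
        pair = interactions.LRPair("planted", ("lig",), ("rec",))
        rr = interactions.permutation_test(
            a2, "cluster", [pair], nperm=1000, seed=_seed(seed, 500 + j),
            combos=[(pair, "A", "B")],
        )
        hits += bool(rr["pval"].iloc[0] <= 0.01)
    return {
        "lr_type1_rate": rate,
        "lr_planted_pair_hit_rate": hits / n_seeds,
    }


# 8 -------------------------------------------------------------------------

def hotspot_detection(seed: int, n_seeds: int = 20) -> dict:
    inside, outside = [], []
    for j in range(n_seeds):
        spots = synthetic.simulate_spots(seed=_seed(seed, j))
        per, _ = coloc.neighborhood_correlation(spots, "scoreX", "scoreY")
        hot = spots["in_hotspot"].to_numpy()
        inside.append(per[hot].dropna().mean())
        outside.append(per[~hot].notna().mean())
    ok = np.mean(
        [(i >= 0.6) and (o <= 0.1) for i, o in zip(inside, outside)]
    )
    spots = synthetic.simulate_spots(seed=_seed(seed, 99))
    spots["scoreY"] = spots["scoreX"]
    per, mean_r = coloc.neighborhood_correlation(spots, "scoreX", "scoreY")
    return {
        "hotspot_mean_retained_r_inside": float(np.mean(inside)),
        "hotspot_retained_fraction_outside": float(np.mean(outside)),
        "hotspot_seed_pass_fraction": float(ok),
        "identical_scores_mean_r": float(mean_r),
    }


# 9 -------------------------------------------------------------------------

def grid_colocalization(seed: int, n_seeds: int = 20) -> dict:
    c = synthetic.simulate_centroids(
        {"A": 400, "B": 400}, coupling=0.0, seed=_seed(seed, 0)
    )
    r0, _ = coloc.grid_correlation(coloc.grid_bin(c), "A", "B")
    null_abs = []
    for j in range(n_seeds):
        c = synthetic.simulate_centroids(
            {"A": 800, "B": 800}, field=(4000.0, 4000.0), coupling=None,
            seed=_seed(seed, 10 + j),
        )
        table = coloc.grid_bin(c)
        r, _ = coloc.grid_correlation(table, "A", "B")
        null_abs.append(abs(r))
    rng = np.random.default_rng(_seed(seed, 50))
    xy = rng.uniform(0, 100, size=(100, 2))
    spots = pd.DataFrame(
        {"spot_id": [f"s{i}" for i in range(100)], "x": xy[:, 0], "y": xy[:, 1]}
    )
    nbrs = coloc.knn_spot_graph(spots, k=6)
    ok = True
    for i in range(100):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        d[i] = np.inf
        ok &= set(nbrs[i]) == set(np.argsort(d, kind="stable")[:6])
    return {
        "grid_sigma0_r": float(r0),
        "grid_null_within_bound_fraction": float(np.mean(np.array(null_abs) <= 0.2)),
        "grid_coupled_r": float(
            coloc.grid_correlation(
                coloc.grid_bin(
                    synthetic.simulate_centroids(
                        {"A": 2000, "B": 2000}, coupling=20.0, seed=_seed(seed, 40)
                    )
                ),
                "A",
                "B",
            )[0]
        ),
        "knn_matches_brute_force": bool(ok),
    }


# 10 ------------------------------------------------------------------------

def survival_validation(seed: int, n_null: int = 1000, n_power: int = 200) -> dict:
    stat, _ = logrank([1, 3, 2, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
    toy_err = float(abs(stat - (2 - 4 / 3) ** 2 / (26 / 36)))

    rejections = 0
    for j in range(n_null):
        expr, time, event, _ = synthetic.simulate_cohort(
            n_samples=60, n_background_genes=80, hazard_coef=0.0,
            seed=_seed(seed, j),
        )
        cohort = SurvivalCohort(expr, time, event)
        sig = [g for g in expr.columns if g.startswith("SIG")]
        rep = signature_survival(cohort, sig)
        rejections += rep.pval < 0.05
    type1 = rejections / n_null

    power_hits = 0
    for j in range(n_power):
        expr, time, event, _ = synthetic.simulate_cohort(
            n_samples=200, n_background_genes=80, hazard_coef=-1.0,
            seed=_seed(seed, 5000 + j),
        )
        cohort = SurvivalCohort(expr, time, event)
        sig = [g for g in expr.columns if g.startswith("SIG")]
        rep = signature_survival(cohort, sig)
        power_hits += rep.pval < 0.05
    return {
        "logrank_toy_abs_error": toy_err,
        "survival_type1_rate": float(type1),
        "survival_power_beta_minus1": power_hits / n_power,
    }


# 11 ------------------------------------------------------------------------

def pipeline_determinism(seed: int, outdir: str) -> dict:
    cfg = load_config(
        overrides={
            "seed": int(seed),
            "simulate": {"n_genes": 600},
            "qc": {"min_genes": 50, "max_genes": 590},
            "pseudobulk": {"n_boot": 3},
            "gsea": {"nperm": 300},
            "lr": {"nperm": 300},
            "survival": {"n_samples": 80},
        }
    )
    m1 = run_end_to_end(cfg, f"{outdir}/run1")
    m2 = run_end_to_end(cfg, f"{outdir}/run2")
    h1 = [(a["path"], a["sha256"]) for a in m1["artifacts"]]
    h2 = [(a["path"], a["sha256"]) for a in m2["artifacts"]]
    return {"pipeline_manifests_identical": h1 == h2}
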