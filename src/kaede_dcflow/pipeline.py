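"""End-to-end orchestration on synthetic data.

Runs the full analytical narrative — simulate Kaede-labeled cells, QC,
label composition, bootstrapped pseudo-bulk ranking, preranked GSEA of the
planted programs, ligand-receptor permutation testing, spot-neighborhood
and grid co-localization, and signature-stratified survival — writing every
artifact with a manifest of content hashes so that identical configs
reproduce byte-identical runs.

A single global seed is expanded into independent per-stage seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``, so stages
are individually reproducible and do not share streams.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import coloc, gsea, interactions, io, pseudobulk, sc_core, synthetic
from .cohort import SurvivalCohort, signature_survival

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "n_genes": 2000,
        "library_median": 5000.0,
        "treated": False,
    },
    "qc": {
        # bounds scaled to the synthetic gene universe (2k genes, ~5k counts)
        "min_genes": 200,
        "max_genes": 1900,
        "max_mito": 0.075,
        "min_cells_per_gene": 3,
    },
    "pseudobulk": {"contrast": ["S2_DC2", "S3_DC3"], "n_pseudoreps": 3, "n_boot": 11},
    "gsea": {"nperm": 1000, "min_size": 5},
    "lr": {"nperm": 1000, "min_frac": 0.10},
    "spatial": {"k": 6, "alpha": 0.05},
    "grid": {"grid_width": 200.0, "jitter_sigma": 20.0, "n_per_class": 1000},
    "survival": {"n_samples": 200, "hazard_coef": -1.0},
}

STAGES = (
    "simulate",
    "qc",
    "composition",
    "pseudobulk_rank",
    "gsea",
    "lr",
    "spatial",
    "grid",
    "survival",
)


class ConfigError(ValueError):
    pass


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config (and/or an override dict) onto the defaults,
    rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        _merge(user, overrides)
    _validate_and_merge(cfg, user, trail="")
    return cfg


def _merge(base: dict, extra: dict):
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def _validate_and_merge(cfg: dict, user: dict, trail: str):
    for k, v in user.items():
        if k not in cfg:
            raise ConfigError(f"unknown config key {trail + k!r}")
        if isinstance(cfg[k], dict):
            if not isinstance(v, dict):
                raise ConfigError(f"config key {trail + k!r} must be a mapping")
            _validate_and_merge(cfg[k], v, trail + k + ".")
        else:
            cfg[k] = v


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_end_to_end(config: dict, outdir: str) -> dict:
    """Execute every stage in order; returns the manifest dict.

    All stage outputs are written under ``outdir``; the manifest
    (``manifest.json``) records every artifact with its content hash, the
    producing stage and the stage seed, and ``summary.json`` collects the
    headline numbers of the run.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest = {"config": config, "artifacts": []}
    summary = {}

    def record(stage, paths, seed):
        for p in sorted(paths):
            manifest["artifacts"].append(
                {
                    "stage": stage,
                    "path": os.path.relpath(p, outdir),
                    "sha256": _sha256(p),
                    "seed": seed,
                }
            )

    cfg_echo = os.path.join(outdir, "config.yaml")
    with open(cfg_echo, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    state = {}
    for stage in STAGES:
        seed = stage_seed(config["seed"], stage)
        logger.info("running stage %s (seed %d)", stage, seed)
        try:
            paths = _STAGE_FUNCS[stage](config, outdir, seed, state, summary)
        except Exception as exc:  # noqa: BLE001 - stage name is the contract
            raise StageFailure(stage, exc) from exc
        record(stage, paths, seed)

    summary_path = os.path.join(outdir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    record("summary", [summary_path, cfg_echo], config["seed"])
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, outdir, seed, state, summary):
    sim = cfg["simulate"]
    params = synthetic.DwellModelParams()
    cells = synthetic.simulate_dwell(params, seed=seed, treated=sim["treated"])
    program = synthetic.GeneProgram.default(n_genes=sim["n_genes"], seed=seed)
    adata = synthetic.sample_expression(
        cells, program, library_median=sim["library_median"], seed=seed + 1
    )
    state["params"] = params
    state["program"] = program
    state["adata"] = adata
    d = os.path.join(outdir, "celltable")
    paths = io.write_celltable(adata, d)
    gmt = os.path.join(outdir, "planted_sets.gmt")
    io.write_gmt(program.signatures, gmt)
    paths.append(gmt)
    snap = os.path.join(outdir, "dwell_params.yaml")
    with open(snap, "w") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(params).items()},
            fh, sort_keys=True,
        )
    paths.append(snap)
    return paths


def _stage_qc(cfg, outdir, seed, state, summary):
    q = cfg["qc"]
    filtered = sc_core.qc_filter(
        state["adata"],
        min_genes=q["min_genes"],
        max_genes=q["max_genes"],
        max_mito=q["max_mito"],
        min_cells_per_gene=q["min_cells_per_gene"],
    )
    norm = sc_core.lognormalize(filtered)
    state["norm"] = norm
    summary["qc"] = {
        "n_cells_in": int(state["adata"].n_obs),
        "n_cells_kept": int(norm.n_obs),
        "n_genes_kept": int(norm.n_vars),
    }
    path = os.path.join(outdir, "qc_report.json")
    with open(path, "w") as fh:
        json.dump(summary["qc"], fh, indent=2, sort_keys=True)
    return [path]


def _stage_composition(cfg, outdir, seed, state, summary):
    obs = state["norm"].obs
    tumour = obs[obs["tissue"] == "tumour"]
    comp = sc_core.kaede_composition(tumour, groupby="state")
    path = os.path.join(outdir, "kaede_composition.csv")
    io.write_csv(comp, path)
    summary["composition"] = {
        row["group"]: row["red_fraction"] for _, row in comp.iterrows()
    }
    return [path]


def _stage_pseudobulk(cfg, outdir, seed, state, summary):
    pbc = cfg["pseudobulk"]
    norm = state["norm"]
    contrast = tuple(pbc["contrast"])
    mask = norm.obs["state"].isin(contrast) & (norm.obs["tissue"] == "tumour")
    sub = norm[mask].copy()
    sub.X = sub.layers["counts"]
    design = pseudobulk.PseudobulkDesign(
        n_pseudoreps=pbc["n_pseudoreps"], n_boot=pbc["n_boot"], seed=seed
    )
    ranked = pseudobulk.bootstrap_rank(sub, "state", contrast, design)
    state["ranked"] = ranked
    rnk = os.path.join(outdir, "ranking.rnk")
    io.write_rnk(ranked, rnk)
    csv = os.path.join(outdir, "ranking_full.csv")
    io.write_csv(ranked, csv)
    summary["pseudobulk_rank"] = {"top_gene": ranked.iloc[0]["gene"]}
    return [rnk, csv]


def _stage_gsea(cfg, outdir, seed, state, summary):
    g = cfg["gsea"]
    sets = {k: list(v) for k, v in state["program"].signatures.items()}
    res = gsea.prerank_gsea(
        state["ranked"], sets, nperm=g["nperm"], min_size=g["min_size"], seed=seed
    )
    out = res.copy()
    out["leading_edge"] = out["leading_edge"].map(";".join)
    path = os.path.join(outdir, "gsea_results.csv")
    io.write_csv(out, path)
    act = res[res["set"] == "activation"]
    summary["gsea"] = {
        "activation_es": float(act["es"].iloc[0]) if len(act) else None,
        "activation_padj": float(act["padj"].iloc[0]) if len(act) else None,
        "activation_called": bool(
            len(act) and act["es"].iloc[0] > 0 and act["padj"].iloc[0] < 0.05
        ),
    }
    return [path]


def _stage_lr(cfg, outdir, seed, state, summary):
    lrc = cfg["lr"]
    program = state["program"]
    pairs = [
        interactions.LRPair(
            "planted_dc2_ligand",
            (program.signatures["dc2_marker"][0],),
            (program.signatures["antigen_presentation"][0],),
        ),
        interactions.LRPair(
            "null_pair",
            (program.gene_names[-1],),
            (program.gene_names[-2],),
        ),
    ]
    pair_csv = os.path.join(outdir, "lr_pairs.csv")
    pd.DataFrame(
        {
            "pair": [p.name for p in pairs],
            "ligand": [";".join(p.ligand) for p in pairs],
            "receptor": [";".join(p.receptor) for p in pairs],
        }
    ).to_csv(pair_csv, index=False)
    norm = state["norm"]
    tum = norm[norm.obs["tissue"] == "tumour"].copy()
    res = interactions.permutation_test(
        tum, "state", pairs, nperm=lrc["nperm"], min_frac=lrc["min_frac"], seed=seed
    )
    path = os.path.join(outdir, "lr_results.csv")
    io.write_csv(res, path)
    planted = res[
        (res["pair"] == "planted_dc2_ligand")
        & (res["sender"] == "S2_DC2")
        & (res["receiver"] == "S1_DC1")
    ]
    summary["lr"] = {
        "n_significant": int(res["significant"].sum()),
        "planted_pair_p": float(planted["pval"].iloc[0]) if len(planted) else None,
    }
    return [path, pair_csv]


def _stage_spatial(cfg, outdir, seed, state, summary):
    sp = cfg["spatial"]
    spots = synthetic.simulate_spots(seed=seed)
    per_spot, mean_r = coloc.neighborhood_correlation(
        spots, "scoreX", "scoreY", k=sp["k"], alpha=sp["alpha"]
    )
    spots_out = spots.copy()
    spots_out["neighborhood_r"] = per_spot
    path = os.path.join(outdir, "spatial_neighborhoods.csv")
    io.write_csv(spots_out, path)
    r, p = coloc.section_correlation(spots, "scoreX", "scoreY")
    summary["spatial"] = {
        "mean_retained_r": mean_r,
        "section_r": r,
        "n_retained": int(per_spot.notna().sum()),
    }
    return [path]


def _stage_grid(cfg, outdir, seed, state, summary):
    gc = cfg["grid"]
    n = gc["n_per_class"]
    cents = synthetic.simulate_centroids(
        {"A": n, "B": n}, coupling=gc["jitter_sigma"], seed=seed
    )
    table = coloc.grid_bin(cents, grid_width=gc["grid_width"])
    r, p = coloc.grid_correlation(table, "A", "B")
    path = os.path.join(outdir, "grid_counts.csv")
    table.reset_index().to_csv(path, index=False)
    summary["grid"] = {"r": r, "pval": p, "n_grids": int(len(table))}
    return [path]


def _stage_survival(cfg, outdir, seed, state, summary):
    sv = cfg["survival"]
    expr, time, event, _z = synthetic.simulate_cohort(
        n_samples=sv["n_samples"], hazard_coef=sv["hazard_coef"], seed=seed
    )
    cohort = SurvivalCohort(expr, time, event)
    sig = [g for g in expr.columns if g.startswith("SIG")]
    rep = signature_survival(cohort, sig)
    curves_path = os.path.join(outdir, "survival_curves.csv")
    io.write_csv(rep.curves, curves_path)
    cohort_path = os.path.join(outdir, "cohort.csv")
    cohort.to_csv(cohort_path)
    summary["survival"] = {
        "logrank_stat": rep.statistic,
        "logrank_p": rep.pval,
        "median_survival": rep.median_survival,
    }
    return [curves_path, cohort_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "composition": _stage_composition,
    "pseudobulk_rank": _stage_pseudobulk,
    "gsea": _stage_gsea,
    "lr": _stage_lr,
    "spatial": _stage_spatial,
    "grid": _stage_grid,
    "survival": _stage_survival,
}
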