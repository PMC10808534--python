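"""Permutation-based ligand-receptor interaction scoring between clusters.

The interaction score of a ligand-receptor pair for a (sender, receiver)
cluster combination is the arithmetic mean of the ligand's mean normalized
expression in the sender and the receptor's mean in the receiver.  Multi-
subunit sides take the minimum subunit mean.  A side is undefined unless
every subunit is expressed (> 0) in at least ``min_frac`` of the cluster's
cells; undefined sides propagate and such combinations are not tested.
Significance comes from shuffling cluster labels globally across all cells:
``p = (1 + #{permuted score >= observed}) / (1 + nperm)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass(frozen=True)
class LRPair:
    """Named ligand-receptor pair; either side may list several subunits."""

    name: str
    ligand: tuple
    receptor: tuple

    def __post_init__(self):
        if not self.ligand or not self.receptor:
            raise ValueError(f"pair {self.name!r} has an empty subunit list")


def read_lr_pairs(path: str) -> list:
    """3-column CSV: pair name, ';'-joined ligand subunits, ';'-joined
    receptor subunits."""
    df = pd.read_csv(path)
    cols = df.columns[:3]
    return [
        LRPair(str(r[cols[0]]), tuple(str(r[cols[1]]).split(";")), tuple(str(r[cols[2]]).split(";")))
        for _, r in df.iterrows()
    ]


def expressed_mean(
    adata, cluster_mask: np.ndarray, genes, min_frac: float = 0.10
) -> float:
    """Minimum over subunits of the cluster mean normalized expression;
    NaN (undefined) if any subunit is expressed in < ``min_frac`` of the
    cluster's cells."""
    if not np.any(cluster_mask):
        raise ValueError("cluster is empty")
    var_index = pd.Index(adata.var_names)
    idx = var_index.get_indexer(list(genes))
    if (idx < 0).any():
        missing = [g for g, i in zip(genes, idx) if i < 0]
        raise KeyError(f"unknown gene(s): {missing}")
    x = adata.X[np.asarray(cluster_mask)][:, idx]
    dense = x.toarray() if sparse.issparse(x) else np.asarray(x)
    frac = (dense > 0).mean(axis=0)
    if (frac < min_frac).any():
        return float("nan")
    return float(dense.mean(axis=0).min())


def interaction_score(
    adata, pair: LRPair, sender_mask, receiver_mask, min_frac: float = 0.10
) -> float:
    """(ligand mean in sender + receptor mean in receiver) / 2; NaN if
    either side is undefined."""
    lm = expressed_mean(adata, sender_mask, pair.ligand, min_frac)
    rm = expressed_mean(adata, receiver_mask, pair.receptor, min_frac)
    return (lm + rm) / 2.0


def permutation_test(
    adata,
    cluster_col: str,
    pairs,
    nperm: int = 1000,
    min_frac: float = 0.10,
    seed: int = 0,
    combos=None,
) -> pd.DataFrame:
    """CellPhoneDB-style permutation test over all (pair, sender, receiver)
    combinations (or the subset in ``combos``).

    Cluster labels are shuffled globally across cells ``nperm`` times; the
    permuted score keeps the min-subunit rule but not the detection filter,
    which is applied to the observed score only.  Deterministic given seed.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    labels = adata.obs[cluster_col].to_numpy()
    clusters = sorted(pd.unique(labels).tolist())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    genes_needed = sorted(
        {g for p in pairs for g in (*p.ligand, *p.receptor)}
    )
    var_index = pd.Index(adata.var_names)
    gidx = var_index.get_indexer(genes_needed)
    if (gidx < 0).any():
        missing = [g for g, i in zip(genes_needed, gidx) if i < 0]
        raise KeyError(f"unknown gene(s): {missing}")
    gene_col = {g: j for j, g in enumerate(genes_needed)}
    x = adata.X[:, gidx]
    dense = np.asarray(x.toarray() if sparse.issparse(x) else x, dtype=float)
    n_cells = dense.shape[0]

    onehot = np.stack([(labels == c) for c in clusters]).astype(float)
    sizes = onehot.sum(axis=1, keepdims=True)
    cidx = {c: i for i, c in enumerate(clusters)}

    def cluster_means(oh):
        return (oh @ dense) / sizes

    def side_mean(means, cluster, subunits):
        return means[cidx[cluster], [gene_col[g] for g in subunits]].min()

    obs_means = cluster_means(onehot)
    frac = (onehot @ (dense > 0)) / sizes

    if combos is None:
        combos = [
            (p, s, r) for p in pairs for s in clusters for r in clusters
        ]
    records = []
    tested = []
    for p, s, r in combos:
        lig_ok = all(frac[cidx[s], gene_col[g]] >= min_frac for g in p.ligand)
        rec_ok = all(frac[cidx[r], gene_col[g]] >= min_frac for g in p.receptor)
        score = (
            (side_mean(obs_means, s, p.ligand) + side_mean(obs_means, r, p.receptor)) / 2.0
            if (lig_ok and rec_ok)
            else float("nan")
        )
        records.append(
            {"pair": p.name, "sender": s, "receiver": r, "score": score}
        )
        if lig_ok and rec_ok:
            tested.append((len(records) - 1, p, s, r, score))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(tested))
    if tested:
        # padded subunit-index arrays for vectorized permuted scores
        max_l = max(len(t[1].ligand) for t in tested)
        max_r = max(len(t[1].receptor) for t in tested)
        t_n = len(tested)
        lig_cols = np.zeros((t_n, max_l), int)
        lig_pad = np.zeros((t_n, max_l), bool)
        rec_cols = np.zeros((t_n, max_r), int)
        rec_pad = np.zeros((t_n, max_r), bool)
        s_rows = np.empty(t_n, int)
        r_rows = np.empty(t_n, int)
        obs_scores = np.empty(t_n)
        for t, (_row, p, s, r, score) in enumerate(tested):
            s_rows[t], r_rows[t] = cidx[s], cidx[r]
            obs_scores[t] = score
            for j, g in enumerate(p.ligand):
                lig_cols[t, j] = gene_col[g]
            lig_pad[t, len(p.ligand):] = True
            for j, g in enumerate(p.receptor):
                rec_cols[t, j] = gene_col[g]
            rec_pad[t, len(p.receptor):] = True
        label_codes = pd.Categorical(labels, categories=clusters).codes.copy()
        inv_sizes = (1.0 / sizes).ravel()
        code_range = np.arange(len(clusters))
        for _ in range(nperm):
            rng.shuffle(label_codes)
            oh = (label_codes == code_range[:, None]).astype(float)
            pm = (oh @ dense) * inv_sizes[:, None]
            lv = pm[s_rows[:, None], lig_cols]
            lv[lig_pad] = np.inf
            rv = pm[r_rows[:, None], rec_cols]
            rv[rec_pad] = np.inf
            ps = (lv.min(axis=1) + rv.min(axis=1)) / 2.0
            exceed += ps >= obs_scores

    out = pd.DataFrame(records)
    out["pval"] = np.nan
    for t, (row, *_rest) in enumerate(tested):
        out.loc[row, "pval"] = (1.0 + exceed[t]) / (1.0 + nperm)
    out["significant"] = out["pval"] < 0.05
    return out
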