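"""Single-cell core: QC, normalization, signature scoring, Wilcoxon DE,
state-signature extraction, Kaede composition statistics, label transfer.

The cell table is an AnnData (cells x genes).  QC thresholds follow the
strict reading of the filtering rule "cells mapped to > 6000 or < 1000 genes
are removed": boundary cells are retained.  Mitochondrial filtering removes
cells at or above the cut-off (retain < 7.5%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LOG2FC_EPS = 1e-9


@dataclass
class GeneSignature:
    """Named, duplicate-free gene list."""

    name: str
    genes: list

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self):
        return len(self.genes)


def _detected_per_cell(x) -> np.ndarray:
    if sparse.issparse(x):
        return np.asarray((x > 0).sum(axis=1)).ravel()
    return (x > 0).sum(axis=1)


def _detected_per_gene(x) -> np.ndarray:
    if sparse.issparse(x):
        return np.asarray((x > 0).sum(axis=0)).ravel()
    return (x > 0).sum(axis=0)


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 1000,
    max_genes: int = 6000,
    max_mito: float = 0.075,
    min_cells_per_gene: int = 3,
) -> ad.AnnData:
    """Remove low/high-complexity and high-mitochondrial cells, then rarely
    detected genes.

    Cells with detected-gene counts strictly below ``min_genes`` or strictly
    above ``max_genes`` are removed (boundary cells kept); cells with
    ``mito_fraction >= max_mito`` are removed; genes detected in fewer than
    ``min_cells_per_gene`` of the remaining cells are removed.  Cell and gene
    filtering are iterated to a fixpoint (removing genes lowers detected-gene
    counts), which makes the operation idempotent.
    """
    if min_genes >= max_genes:
        raise ValueError("min_genes must be < max_genes")
    if min(min_genes, max_genes, min_cells_per_gene) <= 0 or max_mito <= 0:
        raise ValueError("QC thresholds must be positive")
    out = adata
    for _ in range(100):
        n_detected = _detected_per_cell(out.X)
        keep_cells = (n_detected >= min_genes) & (n_detected <= max_genes)
        if "mito_fraction" in out.obs:
            keep_cells &= out.obs["mito_fraction"].to_numpy() < max_mito
        gene_cells = _detected_per_gene(out.X[keep_cells])
        keep_genes = gene_cells >= min_cells_per_gene
        n_removed = (~keep_cells).sum() + (~keep_genes).sum()
        logger.info(
            "qc_filter pass: removed %d cells, %d genes",
            int((~keep_cells).sum()),
            int((~keep_genes).sum()),
        )
        out = out[keep_cells, keep_genes].copy()
        if n_removed == 0:
            break
    if out.n_obs == 0 or out.n_vars == 0:
        logger.warning("qc_filter produced an empty cell table")
    return out


def lognormalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then log1p."""
    x = adata.X
    totals = np.asarray(x.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"all-zero cells cannot be normalized: {list(adata.obs_names[zero[:5]])}"
        )
    if sparse.issparse(x):
        norm = sparse.diags(target_sum / totals) @ x.tocsr()
        norm.data = np.log1p(norm.data)
    else:
        norm = np.log1p(x * (target_sum / totals)[:, None])
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    out.X = norm
    return out


def score_signature(
    adata: ad.AnnData,
    signature: GeneSignature,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control signature score per cell.

    Genes are sorted by their mean (normalized) expression over all cells and
    cut into ``n_bins`` equal-size bins.  For every signature gene,
    ``ctrl_size`` control genes are sampled without replacement from its bin;
    the score is the mean expression over signature genes minus the mean over
    the pooled control set (signature genes excluded from the controls).
    """
    present = [g for g in signature.genes if g in adata.var_names]
    missing = sorted(set(signature.genes) - set(present))
    if not present:
        raise ValueError(f"no signature gene present in the matrix: {missing[:10]}")
    rng = np.random.default_rng(seed)
    x = adata.X
    dense = x.toarray() if sparse.issparse(x) else np.asarray(x)
    gene_means = dense.mean(axis=0)
    order = np.argsort(gene_means, kind="stable")
    bins = np.array_split(order, n_bins)
    bin_of = np.empty(adata.n_vars, dtype=int)
    for b, idx in enumerate(bins):
        bin_of[idx] = b
    var_index = pd.Index(adata.var_names)
    sig_idx = var_index.get_indexer(present)
    ctrl = set()
    for gi in sig_idx:
        pool = bins[bin_of[gi]]
        take = min(ctrl_size, pool.size)
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl -= set(sig_idx.tolist())
    sig_mean = dense[:, sig_idx].mean(axis=1)
    if ctrl:
        ctrl_mean = dense[:, sorted(ctrl)].mean(axis=1)
    else:
        ctrl_mean = np.zeros(adata.n_obs)
    return sig_mean - ctrl_mean


def wilcoxon_de(
    adata: ad.AnnData, group_a: np.ndarray, group_b: np.ndarray
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test of group A vs group B on
    normalized expression, with BH correction across genes.

    ``group_a`` / ``group_b`` are boolean masks or index arrays over cells.
    Uses exact enumeration when both groups have <= 8 cells and no ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.  log2FC compares ``expm1`` means with a small pseudo-count.
    """
    mask_a = np.zeros(adata.n_obs, bool)
    mask_a[group_a] = True
    mask_b = np.zeros(adata.n_obs, bool)
    mask_b[group_b] = True
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both groups must be non-empty")
    if (mask_a & mask_b).any():
        raise ValueError("groups overlap")
    x = adata.X
    dense = x.toarray() if sparse.issparse(x) else np.asarray(x)
    xa, xb = dense[mask_a], dense[mask_b]
    na, nb = xa.shape[0], xb.shape[0]

    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    log2fc = np.log2((mean_a + LOG2FC_EPS) / (mean_b + LOG2FC_EPS))

    if max(na, nb) <= 8:
        stat = np.empty(dense.shape[1])
        pval = np.empty(dense.shape[1])
        for j in range(dense.shape[1]):
            has_ties = len(np.unique(np.concatenate([xa[:, j], xb[:, j]]))) < na + nb
            res = stats.mannwhitneyu(
                xa[:, j],
                xb[:, j],
                alternative="two-sided",
                method="asymptotic" if has_ties else "exact",
            )
            stat[j] = res.statistic - na * nb / 2.0  # centred U
            pval[j] = res.pvalue
    else:
        stat, pval = _rank_sum_asymptotic(xa, xb)

    padj = multipletests(pval, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": list(adata.var_names),
            "log2fc": log2fc,
            "stat": stat,
            "pval": pval,
            "padj": padj,
        }
    )


def _rank_sum_asymptotic(xa: np.ndarray, xb: np.ndarray):
    """Vectorized tie-corrected normal-approximation rank-sum test."""
    na, nb = xa.shape[0], xb.shape[0]
    n = na + nb
    both = np.vstack([xa, xb])
    ranks = stats.rankdata(both, axis=0)
    ra = ranks[:na].sum(axis=0)
    u = ra - na * (na + 1) / 2.0
    mean_u = na * nb / 2.0
    # tie correction per gene
    tie_term = np.zeros(both.shape[1])
    for j in range(both.shape[1]):
        _, counts = np.unique(both[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    var_u = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    diff = u - mean_u
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff - np.sign(diff) * 0.5) / np.sqrt(var_u)
    z = np.where(var_u > 0, z, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return z, np.minimum(pval, 1.0)


def extract_state_signature(
    de: pd.DataFrame,
    name: str = "state_signature",
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
) -> GeneSignature:
    """Upregulated genes at ``padj < padj_max`` and ``log2fc > lfc_min``
    (strict inequalities), ordered by decreasing log2 fold change."""
    hit = de[(de["padj"] < padj_max) & (de["log2fc"] > lfc_min)]
    hit = hit.sort_values(["log2fc", "gene"], ascending=[False, True])
    if hit.empty:
        logger.warning("no gene passed padj<%g and log2fc>%g", padj_max, lfc_min)
    return GeneSignature(name, hit["gene"].tolist())


def kaede_composition(obs: pd.DataFrame, groupby: str = "cluster") -> pd.DataFrame:
    """Red/green counts and red fraction per group of cells."""
    if "kaede" not in obs:
        raise ValueError("cell metadata lacks a 'kaede' column")
    if obs["kaede"].isna().any():
        raise ValueError("missing kaede labels")
    rows = []
    for group, sub in obs.groupby(groupby, observed=True):
        n_red = int((sub["kaede"] == "red").sum())
        n_green = int((sub["kaede"] == "green").sum())
        rows.append(
            {
                "group": group,
                "n_green": n_green,
                "n_red": n_red,
                "red_fraction": n_red / (n_red + n_green),
            }
        )
    return pd.DataFrame(rows)


def green_count_ratio(
    composition: pd.DataFrame, group_x: str, group_y: str
) -> float:
    """Kaede-green count ratio X : Y (e.g. green CCR7+ DC : green cDC).
    Returns NaN when the denominator group has no green cells."""
    comp = composition.set_index("group")
    gx = comp.loc[group_x, "n_green"]
    gy = comp.loc[group_y, "n_green"]
    return float(gx / gy) if gy > 0 else float("nan")


def label_transfer(
    reference: np.ndarray,
    ref_labels,
    query: np.ndarray,
    n_pcs: int = 50,
    k: int = 15,
):
    """PCA-projection label transfer.

    PCA is fitted on the reference (centered, no scaling); the query is
    projected with the reference loadings and centering; labels are assigned
    by k-nearest-neighbor majority vote in PC space, falling back to the
    single nearest neighbor on a tied vote.  Returns ``(labels, proportions)``
    where proportions is the predicted-label frequency table (sums to 1).
    """
    reference = np.asarray(reference, dtype=float)
    query = np.asarray(query, dtype=float)
    ref_labels = np.asarray(ref_labels)
    if len(np.unique(ref_labels)) < 2:
        raise ValueError("reference must carry >= 2 distinct labels")
    if k > reference.shape[0]:
        raise ValueError("k exceeds reference size")
    n_pcs = min(n_pcs, min(reference.shape) - 1) or 1
    pca = PCA(n_components=n_pcs, svd_solver="full")
    ref_pcs = pca.fit_transform(reference)
    query_pcs = pca.transform(query)
    nn = NearestNeighbors(n_neighbors=k).fit(ref_pcs)
    _, idx = nn.kneighbors(query_pcs)
    pred = np.empty(query.shape[0], dtype=ref_labels.dtype)
    for i, neigh in enumerate(idx):
        votes = pd.Series(ref_labels[neigh]).value_counts()
        top = votes[votes == votes.iloc[0]]
        pred[i] = top.index[0] if len(top) == 1 else ref_labels[neigh[0]]
    proportions = (
        pd.Series(pred).value_counts(normalize=True).rename_axis("label").rename("fraction")
    )
    return pred, proportions.reset_index()
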