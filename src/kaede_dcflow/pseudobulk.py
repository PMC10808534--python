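"""Bootstrapped pseudo-bulk differential expression and gene ranking.

Single cells of each group are randomly partitioned into pseudo-replicates
whose summed counts are treated as bulk libraries: size factors by the
median-of-ratios method, per-gene negative-binomial regression with a Wald
test, and the mean Wald statistic over bootstrap re-partitions as the gene
rank metric.  A pseudo-bulk PCA with top-loading over-representation testing
completes the stage.

The NB fit is a two-group log-link GLM with size-factor offsets, method-of-
moments dispersion (floored at 1e-8, no shrinkage), expected-information
IRLS, and standard errors from the observed Fisher information at the
optimum.  Because the dispersion is a noisy per-gene plug-in at pseudo-bulk
sample sizes, two-sided p-values use a Student-t reference with the
residual degrees of freedom (n_samples - 2) rather than the normal; this is
the standard small-sample correction and keeps the null rejection rate near
nominal with 3 replicates per group.  Group levels are fitted in canonical
(sorted) order and the sign of the contrast applied afterwards, so swapping
group labels negates the log2 fold change and Wald statistic exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
LN2 = np.log(2.0)


@dataclass(frozen=True)
class PseudobulkDesign:
    """Bootstrap design: pseudo-replicates per group and iteration count.

    ``n_boot`` defaults to 11 bootstrap re-partitions; ``n_pseudoreps`` to 3
    per group (smallest replicate count supporting dispersion estimation).
    """

    n_pseudoreps: int = 3
    n_boot: int = 11
    seed: int = 0

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.n_pseudoreps < 2:
            raise ValueError("n_pseudoreps must be >= 2")


def partition_pseudoreps(counts, n_reps: int, rng) -> np.ndarray:
    """Randomly split cells (rows of ``counts``) into ``n_reps`` near-equal
    disjoint subsets and sum counts per subset.

    Returns a genes x n_reps matrix.  Subset sizes differ by at most one;
    total counts are conserved exactly.
    """
    rng = np.random.default_rng(rng)
    n_cells = counts.shape[0]
    if n_cells < n_reps:
        raise ValueError(f"group of {n_cells} cells cannot form {n_reps} pseudo-replicates")
    perm = rng.permutation(n_cells)
    cols = []
    for chunk in np.array_split(perm, n_reps):
        block = counts[chunk]
        total = block.sum(axis=0)
        cols.append(np.asarray(total).ravel())
    return np.column_stack(cols)


def size_factors_median_ratios(pseudobulk: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with positive counts in every sample (positive
    geometric mean); each sample's factor is the median over reference genes
    of count / gene geometric mean.
    """
    k = np.asarray(pseudobulk, dtype=float)
    ref = (k > 0).all(axis=1)
    if not ref.any():
        raise ValueError("no gene has positive counts in every sample")
    logk = np.log(k[ref])
    log_geomean = logk.mean(axis=1, keepdims=True)
    log_s = np.median(logk - log_geomean, axis=0)
    log_s = log_s - log_s.mean()  # geometric mean 1
    return np.exp(log_s)


def _mom_dispersion(q: np.ndarray, group_means: np.ndarray, inv_s: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion per gene from normalized counts.

    Var(q_j) = mu_j / s_j + alpha * mu_j^2 with mu_j the group mean; solves
    for alpha with a small-sample df correction (2 fitted means)."""
    n = q.shape[1]
    resid_sq = (q - group_means) ** 2
    num = (resid_sq - group_means * inv_s).sum(axis=1) / max(n - 2, 1)
    den = (group_means**2).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = num / den
    return np.clip(np.nan_to_num(alpha, nan=DISPERSION_FLOOR), DISPERSION_FLOOR, None)


def nb_wald(
    pseudobulk: np.ndarray,
    size_factors: np.ndarray,
    groups,
    contrast: tuple | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene two-group NB Wald test on pseudo-bulk counts.

    Parameters
    ----------
    pseudobulk : genes x samples count matrix
    size_factors : per-sample positive factors (log used as offset)
    groups : per-sample group labels (exactly two levels, >= 2 samples each)
    contrast : (numerator, denominator) group pair; defaults to
        (second, first) of the sorted levels, i.e. positive log2FC means
        higher in the later-sorting group.

    Returns a DataFrame with gene index and columns ``log2fc, stat, se,
    pval, converged``.  Genes with all-zero counts in one group receive a
    0.5 pseudo-count before fitting so the fold change stays finite.
    """
    k = np.asarray(pseudobulk, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    if contrast is None:
        contrast = (levels[1], levels[0])
    if sorted(contrast) != levels:
        raise ValueError(f"contrast {contrast} does not match groups {levels}")
    flip = -1.0 if (contrast[0], contrast[1]) != (levels[1], levels[0]) else 1.0

    x = (groups == levels[1]).astype(float)  # canonical design column
    if x.sum() < 2 or (1 - x).sum() < 2:
        raise ValueError("each group needs >= 2 pseudo-replicates")
    s = np.asarray(size_factors, dtype=float)
    offset = np.log(s)

    zero_in_group = np.zeros(k.shape[0], bool)
    for g in (0.0, 1.0):
        zero_in_group |= (k[:, x == g] == 0).all(axis=1)
    k = k + np.where(zero_in_group, 0.5, 0.0)[:, None]

    q = k / s
    m0 = q[:, x == 0].mean(axis=1)
    m1 = q[:, x == 1].mean(axis=1)
    group_means = np.where(x[None, :] == 1, m1[:, None], m0[:, None])
    alpha = _mom_dispersion(q, group_means, 1.0 / s)

    # IRLS, vectorized over genes; design is (1, x)
    guard = 1e-8
    beta0 = np.log(np.maximum(m0, guard))
    beta1 = np.log(np.maximum(m1, guard)) - beta0
    converged = np.zeros(k.shape[0], bool)
    active = np.ones(k.shape[0], bool)
    for _ in range(max_iter):
        eta = offset[None, :] + beta0[:, None] + beta1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -50, 50))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (k - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swx2 = (w * x * x).sum(axis=1)
        b1 = (w * z).sum(axis=1)
        b2 = (w * x * z).sum(axis=1)
        det = sw * swx2 - swx**2
        ok = det > 1e-300
        new0 = np.where(ok, (swx2 * b1 - swx * b2) / np.where(ok, det, 1.0), beta0)
        new1 = np.where(ok, (sw * b2 - swx * b1) / np.where(ok, det, 1.0), beta1)
        step = np.maximum(np.abs(new0 - beta0), np.abs(new1 - beta1))
        done = step < tol * (1.0 + np.maximum(np.abs(new0), np.abs(new1)))
        beta0, beta1 = new0, new1
        converged |= active & done & ok
        active &= ~done
        if not active.any():
            break

    # observed Fisher information at the optimum
    eta = offset[None, :] + beta0[:, None] + beta1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -50, 50))
    a = alpha[:, None]
    w_obs = mu * (1.0 + a * k) / (1.0 + a * mu) ** 2
    i11 = w_obs.sum(axis=1)
    i12 = (w_obs * x).sum(axis=1)
    i22 = (w_obs * x * x).sum(axis=1)
    det = i11 * i22 - i12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = i11 / det
    se = np.sqrt(np.maximum(var_b1, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = beta1 / se
    bad = ~converged | ~np.isfinite(stat)
    stat = np.where(bad, np.nan, stat) * flip
    df_resid = k.shape[1] - 2
    pval = 2.0 * stats.t.sf(np.abs(stat), df_resid)
    return pd.DataFrame(
        {
            "log2fc": flip * beta1 / LN2,
            "stat": stat,
            "se": se,
            "pval": pval,
            "converged": ~bad,
        }
    )


def _group_counts(adata_or_counts, mask):
    x = adata_or_counts.X if hasattr(adata_or_counts, "X") else adata_or_counts
    sub = x[np.asarray(mask)]
    return sub


def bootstrap_rank(
    adata,
    group_col: str,
    contrast: tuple,
    design: PseudobulkDesign = PseudobulkDesign(),
    return_stats: bool = False,
):
    """Mean-Wald bootstrap gene ranking between two cell groups.

    For each of ``design.n_boot`` iterations the cells of each group are
    independently re-partitioned into pseudo-replicates, size factors are
    recomputed, and the NB Wald statistic is collected; the rank metric is
    the mean statistic over iterations where the gene converged.  The output
    is sorted descending with an alphabetical tie-break; genes that never
    converged are placed last and flagged.
    """
    labels = adata.obs[group_col].to_numpy()
    num, den = contrast
    mask_a = labels == num
    mask_b = labels == den
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"empty group in contrast {contrast}")
    counts_a = _group_counts(adata, mask_a)
    counts_b = _group_counts(adata, mask_b)
    rng = np.random.default_rng(design.seed)
    stats_mat = np.full((adata.n_vars, design.n_boot), np.nan)
    for b in range(design.n_boot):
        pb_a = partition_pseudoreps(counts_a, design.n_pseudoreps, rng)
        pb_b = partition_pseudoreps(counts_b, design.n_pseudoreps, rng)
        pb = np.hstack([pb_a, pb_b])
        grp = np.array([num] * design.n_pseudoreps + [den] * design.n_pseudoreps)
        sf = size_factors_median_ratios(pb)
        res = nb_wald(pb, sf, grp, contrast=contrast)
        stats_mat[:, b] = res["stat"].to_numpy()
    with np.errstate(invalid="ignore"):
        metric = np.nanmean(stats_mat, axis=1)
    n_conv = np.isfinite(stats_mat).sum(axis=1)
    ranked = pd.DataFrame(
        {
            "gene": list(adata.var_names),
            "score": metric,
            "n_converged": n_conv,
        }
    )
    never = ranked["score"].isna()
    ranked["score"] = ranked["score"].fillna(-np.inf)
    ranked["flagged"] = never
    ranked = ranked.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if return_stats:
        return ranked, stats_mat
    return ranked


def pseudobulk_pca(
    pseudobulk: np.ndarray, size_factors: np.ndarray, n_components: int = 10
):
    """PCA of log1p size-factor-normalized pseudo-bulk samples.

    Returns ``(components, loadings, variance_ratio)`` with components
    samples x PCs and loadings genes x PCs (orthonormal columns)."""
    k = np.asarray(pseudobulk, dtype=float)
    y = np.log1p(k / np.asarray(size_factors)).T  # samples x genes
    max_rank = min(y.shape[0] - 1, y.shape[1])
    if n_components > max_rank:
        import warnings

        warnings.warn(
            f"n_components truncated from {n_components} to rank {max_rank}",
            stacklevel=2,
        )
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    comps = pca.fit_transform(y)
    return comps, pca.components_.T, pca.explained_variance_ratio_


def top_loading_genes(loadings: np.ndarray, gene_names, component: int = 0, n_top: int = 100):
    """Genes with the largest absolute loading on one component."""
    order = np.argsort(-np.abs(loadings[:, component]), kind="stable")
    return [gene_names[i] for i in order[:n_top]]


def hypergeom_ora(top_genes, gene_sets: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``top_genes`` in each
    gene set, BH-adjusted across the collection."""
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    draw = [g for g in top_genes if g in uni]
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & uni
        overlap = len(members & set(draw))
        p = stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(draw))
        rows.append({"set": name, "overlap": overlap, "set_size": len(members), "pval": p})
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["pval"], method="fdr_bh")[1]
    return out
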