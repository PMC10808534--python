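"""Preranked gene-set enrichment and single-sample GSEA.

The enrichment score (ES) is the extremum of the weighted Kolmogorov-Smirnov
running sum over a ranked gene list: hits add ``|metric|**w`` normalised by
the total hit weight, misses subtract ``1/(N - N_hits)``.  Significance uses
a gene-set permutation null (random same-size sets from the ranked
universe), one-sided within the sign of the observed ES with the +1
correction; NES divides the ES by the mean absolute null ES of the same
sign.  BH adjustment is applied across the retained set collection and the
headline output is the signed log p, ``sign(ES) * -log10(padj)``.

ssGSEA scores a single expression profile as the summed difference between
the weighted in-set and unweighted out-set empirical CDFs over the sample's
own descending gene ranking (rank weights ``rank**exponent``).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    pval: float
    padj: float
    signed_logp: float = float("nan")
    leading_edge: list = field(default_factory=list)


def es_score(
    genes, metrics, gene_set, weight_exponent: float = 1.0
):
    """Running-sum enrichment score of ``gene_set`` in the ranked list.

    ``genes`` must already be ordered by decreasing metric.  Returns
    ``(es, running_sum, leading_edge)``.
    """
    genes = list(genes)
    metrics = np.asarray(metrics, dtype=float)
    hit = np.array([g in set(gene_set) for g in genes])
    n = len(genes)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked list; no misses to walk")
    w = np.abs(metrics) ** weight_exponent
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit metrics are zero: fall back to equal weights
        hit_w = hit.astype(float)
        total = hit_w.sum()
    running = np.cumsum(hit_w / total - (~hit) / (n - n_hit))
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]
    return es, running, leading


def _es_from_positions(pos, w, n):
    """Vectorized ES for hit-position matrices.

    pos: (B, m) sorted hit positions (0-based); w: per-position weights of
    the ranked list.  The running-sum extremum is attained either right
    after a hit (peaks) or just before a hit (troughs), so only 2m
    candidates need evaluation per set.
    """
    m = pos.shape[1]
    hw = w[pos]
    tot = hw.sum(axis=1, keepdims=True)
    zero = tot == 0
    if np.any(zero):  # degenerate all-zero weights: equal weighting
        hw = np.where(zero, 1.0, hw)
        tot = np.where(zero, float(m), tot)
    cum_hit = np.cumsum(hw, axis=1) / tot
    t = np.arange(1, m + 1)
    miss_after = (pos + 1 - t) / (n - m)  # misses seen once the t-th hit is passed
    peaks = cum_hit - miss_after
    troughs = np.concatenate(
        [np.zeros((pos.shape[0], 1)), cum_hit[:, :-1]], axis=1
    ) - (pos - (t - 1)) / (n - m)
    cand = np.concatenate([peaks, troughs], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(cand.shape[0]), idx]


def prerank_gsea(
    ranked: pd.DataFrame,
    gene_sets: dict,
    nperm: int = 10000,
    min_size: int = 5,
    weight_exponent: float = 1.0,
    seed: int = 0,
    null: str = "sampled",
    max_exhaustive: int = 200000,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    Parameters
    ----------
    ranked : DataFrame with ``gene`` and ``score`` columns, any order
        (sorted internally, descending score with alphabetical tie-break).
    null : "sampled" draws ``nperm`` random same-size sets; "exhaustive"
        enumerates every same-size subset when their number is at most
        ``max_exhaustive`` (p-values are then exact).
    """
    ranked = ranked.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    genes = ranked["gene"].tolist()
    metrics = ranked["score"].to_numpy(dtype=float)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    w = np.abs(metrics) ** weight_exponent
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in gene_sets.items():
        pos = np.array(sorted(gene_pos[g] for g in set(members) if g in gene_pos))
        if pos.size < min_size:
            continue
        m = pos.size
        if m == n:
            logger.warning("set %s covers the whole universe; skipped", name)
            continue
        es, _, leading = es_score(genes, metrics, set(members), weight_exponent)
        if null == "exhaustive":
            from math import comb

            if comb(n, m) > max_exhaustive:
                raise ValueError(
                    f"exhaustive null infeasible for C({n},{m}) subsets"
                )
            null_pos = np.array(list(itertools.combinations(range(n), m)))
            null_es = _es_from_positions(null_pos, w, n)
        else:
            chunks = []
            left = nperm
            while left > 0:
                b = min(left, 2000)
                null_pos = np.argsort(rng.random((b, n)), axis=1)[:, :m]
                null_pos.sort(axis=1)
                chunks.append(_es_from_positions(null_pos, w, n))
                left -= b
            null_es = np.concatenate(chunks)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            pval = 1.0 / (null_es.size + 1)
            nes = np.nan
        else:
            extreme = np.abs(null_es[same_sign]) >= abs(es)
            if null == "exhaustive":
                pval = extreme.sum() / n_same
            else:
                pval = (1 + extreme.sum()) / (1 + n_same)
            mean_null = np.abs(null_es[same_sign]).mean()
            nes = es / mean_null if mean_null > 0 else np.nan
        rows.append(
            {
                "set": name,
                "size": m,
                "es": es,
                "nes": nes,
                "pval": float(pval),
                "leading_edge": leading,
            }
        )
    if not rows:
        warnings.warn("no gene set passed the min_size filter", stacklevel=2)
        return pd.DataFrame(
            columns=["set", "size", "es", "nes", "pval", "padj", "signed_logp", "leading_edge"]
        )
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["pval"], method="fdr_bh")[1]
    resolution = 1.0 / (nperm + 1)
    out["signed_logp"] = [
        signed_logp(es, padj, resolution) for es, padj in zip(out["es"], out["padj"])
    ]
    return out[["set", "size", "es", "nes", "pval", "padj", "signed_logp", "leading_edge"]]


def signed_logp(es: float, padj: float, resolution: float = 1e-5) -> float:
    """``sign(ES) * -log10(padj)``; 0 when padj = 1; padj = 0 is clamped at
    the permutation resolution with a warning."""
    if padj == 0:
        warnings.warn(
            "padj = 0 clamped at the permutation resolution", stacklevel=2
        )
        padj = resolution
    if not 0 < padj <= 1:
        raise ValueError("padj must lie in (0, 1]")
    if padj == 1.0:
        return 0.0
    return float(np.sign(es) * -np.log10(padj))


def ssgsea(expression: pd.Series, gene_set, exponent: float = 0.25) -> float:
    """Single-sample enrichment score of one expression profile.

    Genes are ranked descending by expression (alphabetical tie-break);
    the score sums, over all ranked positions, the difference between the
    rank-weighted in-set ECDF and the unweighted out-set ECDF.
    """
    expr = expression.sort_index()
    order = np.lexsort((expr.index.to_numpy(), -expr.to_numpy()))
    genes = expr.index.to_numpy()[order]
    n = len(genes)
    in_set = np.isin(genes, list(gene_set))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("expression profile covers no gene of the set")
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets rank N
    wts = np.where(in_set, ranks**exponent, 0.0)
    cdf_in = np.cumsum(wts) / wts.sum()
    if m == n:
        cdf_out = np.zeros(n)
    else:
        cdf_out = np.cumsum(~in_set) / (n - m)
    return float((cdf_in - cdf_out).sum())


def ssgsea_matrix(
    expr: pd.DataFrame, gene_set, exponent: float = 0.25
) -> pd.Series:
    """ssGSEA score per row (sample) of a samples x genes frame."""
    return pd.Series(
        {s: ssgsea(expr.loc[s], gene_set, exponent) for s in expr.index},
        name="ssgsea",
    )


def normalize_01(scores) -> np.ndarray:
    """Scale scores across samples to [0, 1]; constant input maps to all
    zeros.  A single sample has no range and is an error."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("normalize_01 needs >= 2 samples")
    rng_ = x.max() - x.min()
    if rng_ == 0:
        return np.zeros_like(x)
    return (x - x.min()) / rng_
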