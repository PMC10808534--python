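"""Spatial co-localization statistics.

Two complementary measures of whether two signals co-occur in tissue space:

* spot transcriptomics: Pearson correlation of two score vectors over each
  spot's k-nearest-neighbor neighborhood (the spot plus its k = 6 nearest
  neighbors), retained only where both scores are detected at every
  neighborhood spot and the correlation is significant (two-sided t test,
  df = k - 1, p < alpha); the section summary is the mean retained R;
* segmented microscopy: centroids binned into fixed-width square grids
  (200 um) and Pearson correlation of the per-grid counts of two classes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist


def knn_spot_graph(spots: pd.DataFrame, k: int = 6) -> np.ndarray:
    """Euclidean k nearest neighbors per spot (ties broken by row order).

    Returns an (n_spots, k) integer array of row indices."""
    n = len(spots)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} spots, got {n}")
    xy = spots[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates")
    d = cdist(xy, xy)
    np.fill_diagonal(d, np.inf)
    idx = np.argsort(d, axis=1, kind="stable")[:, :k]
    return idx


def neighborhood_correlation(
    spots: pd.DataFrame,
    score_x: str,
    score_y: str,
    k: int = 6,
    alpha: float = 0.05,
    detected=lambda v: v != 0,
) -> tuple[pd.Series, float]:
    """Per-spot neighborhood Pearson R with detection and significance
    filters; returns ``(per_spot_R, section_mean)``.

    A neighborhood is the spot plus its k nearest neighbors (k+1 values).
    The R is assigned to the center spot only if both scores satisfy the
    detection predicate at every neighborhood spot, neither score is
    constant over the neighborhood, and the correlation's two-sided t-test
    p (df = k - 1) is below ``alpha``.  Non-retained spots carry NaN."""
    neighbors = knn_spot_graph(spots, k=k)
    xv = spots[score_x].to_numpy(dtype=float)
    yv = spots[score_y].to_numpy(dtype=float)
    det = detected(xv) & detected(yv)
    out = np.full(len(spots), np.nan)
    for i in range(len(spots)):
        hood = np.concatenate([[i], neighbors[i]])
        if not det[hood].all():
            continue
        xs, ys = xv[hood], yv[hood]
        if xs.std() == 0 or ys.std() == 0:
            continue
        r, p = stats.pearsonr(xs, ys)
        if p < alpha:
            out[i] = r
    per_spot = pd.Series(out, index=spots.index, name="neighborhood_r")
    retained = per_spot.dropna()
    section_mean = float(retained.mean()) if len(retained) else float("nan")
    return per_spot, section_mean


def section_correlation(
    spots: pd.DataFrame, score_x: str, score_y: str
) -> tuple[float, float]:
    """Global Pearson R and p over all spots (t reference, df = n - 2)."""
    if len(spots) < 3:
        raise ValueError("need >= 3 spots")
    xv = spots[score_x].to_numpy(dtype=float)
    yv = spots[score_y].to_numpy(dtype=float)
    if xv.std() == 0 or yv.std() == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)


def grid_bin(centroids: pd.DataFrame, grid_width: float = 200.0) -> pd.DataFrame:
    """Bin centroid detections into half-open square grids of
    ``grid_width``.

    The origin is the data minimum; bins are [a, a+w) x [b, b+w), so a
    detection exactly on an interior boundary falls in the higher bin.
    Only occupied bins are emitted.  Returns a bins x classes count table
    indexed by (gx, gy)."""
    if grid_width <= 0:
        raise ValueError("grid_width must be > 0")
    if centroids.empty:
        raise ValueError("empty centroid table")
    x = centroids["x"].to_numpy(dtype=float)
    y = centroids["y"].to_numpy(dtype=float)
    gx = np.floor((x - x.min()) / grid_width).astype(int)
    gy = np.floor((y - y.min()) / grid_width).astype(int)
    df = pd.DataFrame({"gx": gx, "gy": gy, "cell_class": centroids["cell_class"].to_numpy()})
    table = (
        df.groupby(["gx", "gy", "cell_class"], observed=True)
        .size()
        .unstack("cell_class", fill_value=0)
    )
    return table


def grid_correlation(
    grid_counts: pd.DataFrame, class_a: str, class_b: str
) -> tuple[float, float]:
    """Pearson R and p across occupied grids of two class counts."""
    if len(grid_counts) < 3:
        raise ValueError("need >= 3 occupied grids")
    a = grid_counts.get(class_a)
    b = grid_counts.get(class_b)
    if a is None or b is None:
        raise KeyError(f"class missing from grid table: {class_a!r} or {class_b!r}")
    a = a.to_numpy(dtype=float)
    b = b.to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in a class: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
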