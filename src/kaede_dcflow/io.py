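"""File-format plumbing: MTX+TSV+CSV cell tables, GMT gene sets, RNK rankings.

All writers emit plain text with a fixed float format so that identical
inputs produce byte-identical files (the pipeline manifest hashes rely on
this).
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

FLOAT_FMT = "%.10g"


def write_celltable(adata: ad.AnnData, outdir: str) -> list:
    """Write counts as gene x cell MTX plus gene/barcode TSVs and a metadata
    CSV; returns the list of paths written."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    mtx = os.path.join(outdir, "matrix.mtx")
    mmwrite(mtx, sparse.coo_matrix(x.T.astype(int)))  # genes x cells
    paths.append(mtx)
    genes = os.path.join(outdir, "genes.tsv")
    pd.Series(adata.var_names).to_csv(genes, sep="\t", index=False, header=False)
    paths.append(genes)
    barcodes = os.path.join(outdir, "barcodes.tsv")
    pd.Series(adata.obs_names).to_csv(barcodes, sep="\t", index=False, header=False)
    paths.append(barcodes)
    meta = os.path.join(outdir, "metadata.csv")
    adata.obs.to_csv(meta, float_format=FLOAT_FMT)
    paths.append(meta)
    return paths


def read_celltable(indir: str) -> ad.AnnData:
    """Read a cell table written by :func:`write_celltable`."""
    x = sparse.csr_matrix(mmread(os.path.join(indir, "matrix.mtx")).T)
    genes = pd.read_csv(
        os.path.join(indir, "genes.tsv"), sep="\t", header=None
    )[0].astype(str)
    barcodes = pd.read_csv(
        os.path.join(indir, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    obs = pd.read_csv(os.path.join(indir, "metadata.csv"), index_col=0)
    obs.index = obs.index.astype(str)
    obs = obs.loc[barcodes]
    return ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=genes.values))


def read_gmt(path: str) -> dict:
    """Tab-separated GMT: name, description, genes...  Case-sensitive."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_rnk(path: str) -> pd.DataFrame:
    """Two-column RNK (gene, score), highest score first."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    return df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


def write_rnk(ranked: pd.DataFrame, path: str) -> None:
    ranked[["gene", "score"]].to_csv(
        path, sep="\t", header=False, index=False, float_format=FLOAT_FMT
    )


def write_csv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)
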