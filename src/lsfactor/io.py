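"""Readers and writers for the package's plain-text interchange formats.

Cell matrices travel as MTX triplets (genes x cells, Cell Ranger
orientation) with ``genes.tsv`` / ``barcodes.tsv`` sidecars plus per-cell
and per-sample TSV metadata; pseudobulk matrices as TSV with a JSON sidecar
recording construction parameters and imputed entries.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .preprocess import PseudobulkMatrix

__all__ = ["write_cells", "read_cells", "write_pseudobulk", "read_pseudobulk"]


def write_cells(cells: ad.AnnData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = cells.X if sp.issparse(cells.X) else sp.csr_matrix(np.asarray(cells.X))
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    pd.Series(cells.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cells.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    cells.obs.to_csv(outdir / "cells.tsv", sep="\t")
    samples = cells.uns.get("samples")
    if samples is not None:
        pd.DataFrame(samples).to_csv(outdir / "samples.tsv", sep="\t")


def read_cells(indir) -> ad.AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx"))).T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=X, obs=obs.loc[barcodes], var=pd.DataFrame(index=genes))
    samples_path = indir / "samples.tsv"
    if samples_path.exists():
        adata.uns["samples"] = pd.read_csv(samples_path, sep="\t", index_col=0)
    return adata


def write_pseudobulk(pb: PseudobulkMatrix, outdir, params: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pb.values.to_csv(outdir / "pseudobulk.tsv", sep="\t")
    pb.sample_meta.to_csv(outdir / "samples.tsv", sep="\t")
    sidecar = {
        "standardized": pb.standardized,
        "params": params or {},
        "imputed_entries": (
            [] if pb.imputed is None else [
                [str(s), str(f)]
                for s, f in zip(*np.nonzero(pb.imputed.to_numpy()))
            ]
        ),
    }
    if pb.imputed is not None:
        idx = np.nonzero(pb.imputed.to_numpy())
        sidecar["imputed_entries"] = [
            [str(pb.imputed.index[i]), str(pb.imputed.columns[j])]
            for i, j in zip(*idx)
        ]
    with open(outdir / "pseudobulk.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_pseudobulk(indir) -> PseudobulkMatrix:
    indir = Path(indir)
    values = pd.read_csv(indir / "pseudobulk.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(indir / "samples.tsv", sep="\t", index_col=0)
    sidecar_path = indir / "pseudobulk.json"
    standardized = False
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            standardized = bool(json.load(fh).get("standardized", False))
    return PseudobulkMatrix(values=values, sample_meta=meta, standardized=standardized)
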