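"""Cell-level QC, normalization, and cluster-wise pseudobulk feature construction.

The cell-level container throughout the package is :class:`anndata.AnnData`
with raw counts in ``.X`` and per-cell metadata in ``.obs`` (``sample_id``,
``cluster``, ``n_detected_genes``, ``mito_fraction``, ``ribo_fraction``).
Per-sample metadata lives in ``.uns["samples"]`` as a DataFrame indexed by
sample id.

The sample-level container is :class:`PseudobulkMatrix`: one row per sample,
one column per ``"cluster:gene"`` feature, where each value is the mean
normalized expression of that gene over the sample's cells in that cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "PseudobulkMatrix",
    "filter_cells",
    "normalize",
    "pseudobulk_features",
    "standardize",
    "residualize_covariate",
]


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell quality-control bounds.

    All four bounds are strict: a cell is kept iff
    ``min_genes < n_detected_genes < max_genes`` and
    ``mito_fraction < max_mito`` and ``ribo_fraction < max_ribo``.

    Defaults are the study conventions for skin single-cell data: detected
    genes strictly between 200 and 5,500, mitochondrial fraction below 25%,
    ribosomal fraction below 55%.
    """

    min_genes: int = 200
    max_genes: int = 5500
    max_mito: float = 0.25
    max_ribo: float = 0.55

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be strictly less than max_genes")
        for name in ("max_mito", "max_ribo"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class PseudobulkMatrix:
    """Samples x features matrix of cluster-wise mean expression.

    Attributes
    ----------
    values
        DataFrame, rows = samples, columns = ``"cluster:gene"`` feature names.
    sample_meta
        Per-sample metadata (label, age_group, sex, site_group,
        severity_score, ...) indexed like ``values``.
    standardized
        True once columns have been z-scored (mean 0, unit sample SD).
    imputed
        Optional boolean mask (same shape as ``values``) flagging entries
        that were filled in because the (sample, cluster) combination had no
        cells.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    standardized: bool = False
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.values.isna().any().any():
            raise ValueError("pseudobulk values must be complete (impute first)")

    @property
    def sample_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "PseudobulkMatrix":
        return PseudobulkMatrix(
            values=self.values.copy(),
            sample_meta=self.sample_meta.copy(),
            standardized=self.standardized,
            imputed=None if self.imputed is None else self.imputed.copy(),
        )


def _cell_matrix(cells: ad.AnnData) -> sp.csr_matrix:
    X = cells.X
    if sp.issparse(X):
        return X.tocsr()
    return sp.csr_matrix(np.asarray(X))


def filter_cells(cells: ad.AnnData, thresholds: QCThresholds | None = None) -> ad.AnnData:
    """Retain exactly the cells satisfying the strict QC conjunction.

    Keeps cells with ``min_genes < n_detected_genes < max_genes`` and both
    fraction metrics strictly below their caps. Order and all metadata are
    preserved; an empty result is allowed.
    """
    thresholds = thresholds or QCThresholds()
    obs = cells.obs
    mask = (
        (obs["n_detected_genes"].to_numpy() > thresholds.min_genes)
        & (obs["n_detected_genes"].to_numpy() < thresholds.max_genes)
        & (obs["mito_fraction"].to_numpy() < thresholds.max_mito)
        & (obs["ribo_fraction"].to_numpy() < thresholds.max_ribo)
    )
    out = cells[mask].copy()
    logger.info("filter_cells: kept %d / %d cells", out.n_obs, cells.n_obs)
    return out


def normalize(cells: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Depth-normalize each cell to ``scale`` total counts, then log1p.

    All-zero cells cannot be depth-scaled and are excluded with a warning.
    The transform is monotone per cell, and per-cell depth-invariant:
    doubling a cell's counts leaves its normalized values unchanged.
    """
    totals = np.asarray(_cell_matrix(cells).sum(axis=1)).ravel()
    nonzero = totals > 0
    if not nonzero.all():
        logger.warning("normalize: excluding %d all-zero cells", int((~nonzero).sum()))
    if not nonzero.any():
        raise ValueError("normalize requires at least one cell with nonzero counts")
    out = cells[nonzero].copy()
    out.X = _cell_matrix(out).astype(np.float64)
    sc.pp.normalize_total(out, target_sum=scale)
    sc.pp.log1p(out)
    return out


def pseudobulk_features(
    cells: ad.AnnData,
    top_n: int = 50,
    sample_meta: pd.DataFrame | None = None,
) -> PseudobulkMatrix:
    """Build the samples x "cluster:gene" matrix of top-variance features.

    For each (sample, cluster) pair the feature value is the mean normalized
    expression over that sample's cells in that cluster. Within each cluster,
    the ``top_n`` genes with highest across-sample variance of these
    pseudobulk values are kept (ties broken by lexicographic gene name);
    clusters offering fewer expressed genes contribute all of them, so the
    feature count is ``sum_c min(top_n, p_c)``. With 31 clusters and 50
    genes per cluster this yields the study's 1,550 features.

    Missing (sample, cluster) combinations are imputed with the across-sample
    mean of the feature (i.e., zero on the standardized scale) and flagged in
    the ``imputed`` mask.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if "cluster" not in cells.obs or cells.obs["cluster"].nunique() == 0:
        raise ValueError("no cluster labels present")
    if "sample_id" not in cells.obs:
        raise ValueError("per-cell sample_id labels required")

    X = _cell_matrix(cells).astype(np.float64)
    obs = cells.obs
    genes = np.asarray(cells.var_names)

    if sample_meta is None:
        sample_meta = cells.uns.get("samples")
    if sample_meta is not None:
        sample_meta = pd.DataFrame(sample_meta)
        samples = [s for s in sample_meta.index]
    else:
        samples = sorted(obs["sample_id"].unique())
        sample_meta = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    clusters = sorted(obs["cluster"].astype(str).unique())

    # group means via a sparse (groups x cells) row-normalized indicator
    pairs = list(zip(obs["sample_id"].astype(str), obs["cluster"].astype(str)))
    group_codes, group_ids = pd.factorize(pd.Series(pairs), sort=True)
    counts = np.bincount(group_codes)
    ind = sp.csr_matrix(
        (1.0 / counts[group_codes], (group_codes, np.arange(cells.n_obs))),
        shape=(len(group_ids), cells.n_obs),
    )
    means = np.asarray((ind @ X).todense())  # groups x genes

    group_sample = [g[0] for g in group_ids]
    group_cluster = [g[1] for g in group_ids]

    blocks: list[pd.DataFrame] = []
    imputed_blocks: list[pd.DataFrame] = []
    for cl in clusters:
        rows = [i for i, c in enumerate(group_cluster) if c == cl]
        sub = pd.DataFrame(
            means[rows], index=[group_sample[i] for i in rows], columns=genes
        ).reindex(samples)
        # genes with any expression in this cluster among present samples
        present = sub.notna().any(axis=1)
        expressed = sub.columns[(sub.fillna(0.0) != 0).any(axis=0)]
        sub = sub[expressed]
        var = sub.var(axis=0, ddof=1, skipna=True).fillna(0.0)
        order = sorted(expressed, key=lambda g: (-var[g], g))
        keep = order[: min(top_n, len(order))]
        sub = sub[keep]
        miss = sub.isna()
        if miss.any().any():
            sub = sub.fillna(sub.mean(axis=0, skipna=True))
        sub.columns = [f"{cl}:{g}" for g in keep]
        miss.columns = sub.columns
        blocks.append(sub)
        imputed_blocks.append(miss)
        del present

    values = pd.concat(blocks, axis=1)
    imputed = pd.concat(imputed_blocks, axis=1)
    if imputed.any().any():
        logger.warning(
            "pseudobulk_features: imputed %d missing (sample, cluster) entries",
            int(imputed.to_numpy().sum()),
        )
    values.index.name = "sample_id"
    return PseudobulkMatrix(values=values, sample_meta=sample_meta, imputed=imputed)


def standardize(X: PseudobulkMatrix) -> PseudobulkMatrix:
    """Z-score each feature column (sample SD, ddof=1); drop constant columns.

    Raises on a single-sample matrix. Idempotent up to numerical noise.
    """
    if X.n_samples < 2:
        raise ValueError("standardize requires at least 2 samples")
    sd = X.values.std(axis=0, ddof=1)
    constant = sd <= 0
    if constant.any():
        logger.warning("standardize: dropping %d constant features", int(constant.sum()))
    vals = X.values.loc[:, ~constant]
    vals = (vals - vals.mean(axis=0)) / sd[~constant]
    imputed = None if X.imputed is None else X.imputed.loc[:, vals.columns]
    return PseudobulkMatrix(
        values=vals, sample_meta=X.sample_meta, standardized=True, imputed=imputed
    )


def residualize_covariate(y, covariate):
    """Residualize a response on an intercept plus covariate design by OLS.

    Categorical covariates are expanded to indicator columns; numeric ones
    enter linearly. Residuals sum to zero and are orthogonal to the design.
    A constant covariate yields the mean-centered response (with a warning).
    Returns the same container type as ``y`` (Series index preserved).
    """
    y_arr = np.asarray(y, dtype=float)
    cov = pd.Series(np.asarray(covariate)) if not isinstance(covariate, pd.Series) else covariate
    if len(cov) != len(y_arr):
        raise ValueError("response and covariate lengths differ")

    if cov.dtype.kind in "OUSb" or isinstance(cov.dtype, pd.CategoricalDtype):
        D = pd.get_dummies(cov.astype(str), drop_first=True).to_numpy(dtype=float)
    else:
        vals = cov.to_numpy(dtype=float)
        D = vals.reshape(-1, 1) if np.ptp(vals) > 0 else np.empty((len(vals), 0))

    if D.shape[1] == 0:
        logger.warning("residualize_covariate: constant covariate; mean-centering only")
        resid = y_arr - y_arr.mean()
    else:
        design = np.column_stack([np.ones(len(y_arr)), D])
        beta, *_ = np.linalg.lstsq(design, y_arr, rcond=None)
        resid = y_arr - design @ beta

    if isinstance(y, pd.Series):
        return pd.Series(resid, index=y.index, name=y.name)
    return resid
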