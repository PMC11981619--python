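"""Shared fixtures: scaled-down synthetic cohorts and hand-built cell sets."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lsfactor import CohortConfig, QCThresholds, plant_pseudobulk


SMALL_QC = QCThresholds(min_genes=5, max_genes=5500, max_mito=0.25, max_ribo=0.55)


def small_cohort(seed: int = 0, **kw) -> CohortConfig:
    """Study-sized cohort (44 samples) over a scaled-down gene panel."""
    defaults = dict(n_clusters=10, genes_per_cluster_pool=30, cells_per_sample=(20, 30))
    defaults.update(kw)
    return CohortConfig(seed=seed, **defaults)


@pytest.fixture(scope="session")
def planted_default():
    """One planted 44-sample cohort with a binary response (K=10, snr=5)."""
    cfg = small_cohort(seed=3)
    return plant_pseudobulk(cfg, K=10, snr=5.0)


def cells_from_metrics(metrics) -> ad.AnnData:
    """AnnData whose obs QC columns are set directly from (genes, mito, ribo)."""
    n = len(metrics)
    obs = pd.DataFrame(
        {
            "sample_id": ["S1"] * n,
            "cluster": ["c0"] * n,
            "n_detected_genes": [m[0] for m in metrics],
            "mito_fraction": [m[1] for m in metrics],
            "ribo_fraction": [m[2] for m in metrics],
        },
        index=[f"cell{i}" for i in range(n)],
    )
    X = sp.csr_matrix(np.ones((n, 4)))
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=[f"g{j}" for j in range(4)]))


def cells_from_counts(counts, sample_ids, clusters, gene_names=None) -> ad.AnnData:
    """AnnData from a dense count matrix with consistent QC metadata."""
    counts = np.asarray(counts, dtype=float)
    n, p = counts.shape
    gene_names = gene_names or [f"g{j}" for j in range(p)]
    obs = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "cluster": list(clusters),
            "n_detected_genes": (counts > 0).sum(axis=1),
            "mito_fraction": 0.0,
            "ribo_fraction": 0.0,
        },
        index=[f"cell{i}" for i in range(n)],
    )
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=pd.DataFrame(index=gene_names))
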