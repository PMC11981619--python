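"""Synthetic single-cell cohorts with planted overlapping latent structure.

Two mutually consistent generators back the whole pipeline:

* :func:`simulate_cells` draws a cell-by-gene negative-binomial count matrix
  for a case/control skin cohort (default 27 cases / 17 controls with
  adult/pediatric substructure, 31 cell clusters), including per-cell QC
  metrics and a configurable minority of QC-violating cells, so that the
  filtering -> normalization -> pseudobulk path is exercised end to end.

* :func:`plant_pseudobulk` generates a sample-by-feature pseudobulk matrix
  directly from a known overlapping factor model X = Z A' + E together with
  a binary or continuous response driven by a sparse subset of the factors.
  The full ground truth (:class:`PlantedTruth`) is returned so recovery,
  selection-FDR, and transfer behaviour can be scored against it.

Every draw is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .preprocess import PseudobulkMatrix, QCThresholds

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "PlantedTruth",
    "simulate_cells",
    "plant_pseudobulk",
    "simulate_transfer_cohort",
]

# number of dedicated mitochondrial / ribosomal genes appended to the panel
_N_MITO = 10
_N_RIBO = 15


@dataclass(frozen=True)
class CohortConfig:
    """Sizes and labels of a synthetic cohort.

    Defaults mirror the study design: 27 cases (13 adult, 14 pediatric) and
    17 controls (8 adult, 9 pediatric), 31 cell clusters, a pool of 50 genes
    per cluster. ``n_case`` / ``n_control`` are derived from the subgroup
    counts, so the sum invariant holds by construction. The seed fully
    determines all draws.
    """

    n_adult_case: int = 13
    n_ped_case: int = 14
    n_adult_control: int = 8
    n_ped_control: int = 9
    n_clusters: int = 31
    genes_per_cluster_pool: int = 50
    cells_per_sample: tuple[int, int] = (250, 450)
    site_labels: tuple[str, ...] = ("trunk", "extremity")
    sex_labels: tuple[str, ...] = ("F", "M")
    qc_violation_rate: float = 0.05
    nb_dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_adult_case,
            self.n_ped_case,
            self.n_adult_control,
            self.n_ped_control,
            self.n_clusters,
            self.genes_per_cluster_pool,
        )
        if any(c <= 0 for c in counts[:4]) or self.n_clusters < 1 or self.genes_per_cluster_pool < 1:
            raise ValueError("cohort sizes, cluster count and gene pool must be positive")
        lo, hi = self.cells_per_sample
        if lo <= 0 or hi < lo:
            raise ValueError("cells_per_sample must be a positive (low, high) range")
        if not 0.0 <= self.qc_violation_rate < 1.0:
            raise ValueError("qc_violation_rate must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    @property
    def n_case(self) -> int:
        return self.n_adult_case + self.n_ped_case

    @property
    def n_control(self) -> int:
        return self.n_adult_control + self.n_ped_control

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control

    @property
    def n_features(self) -> int:
        return self.n_clusters * self.genes_per_cluster_pool


@dataclass
class PlantedTruth:
    """Ground truth of a planted pseudobulk draw.

    ``weight_matrix_true`` allocates features to overlapping modules
    (every factor has at least two features loading on it alone; overlap
    features load on exactly two factors with norm-1 rows), and
    ``beta_true`` is nonzero exactly on ``signal_factor_ids``.
    """

    weight_matrix_true: pd.DataFrame  # features x K
    factor_scores_true: pd.DataFrame  # samples x K
    beta_true: pd.Series  # K
    noise_sd: float
    signal_factor_ids: list[str]
    response_kind: str

    @property
    def feature_names(self) -> list[str]:
        return list(self.weight_matrix_true.index)

    @property
    def factor_names(self) -> list[str]:
        return list(self.weight_matrix_true.columns)

    def to_json(self, path) -> None:
        payload = {
            "weight_matrix_true": self.weight_matrix_true.to_dict(orient="split"),
            "factor_scores_true": self.factor_scores_true.to_dict(orient="split"),
            "beta_true": self.beta_true.to_dict(),
            "noise_sd": self.noise_sd,
            "signal_factor_ids": self.signal_factor_ids,
            "response_kind": self.response_kind,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        wm = pd.DataFrame(**payload["weight_matrix_true"])
        fs = pd.DataFrame(**payload["factor_scores_true"])
        return cls(
            weight_matrix_true=wm,
            factor_scores_true=fs,
            beta_true=pd.Series(payload["beta_true"]).reindex(wm.columns),
            noise_sd=payload["noise_sd"],
            signal_factor_ids=payload["signal_factor_ids"],
            response_kind=payload["response_kind"],
        )


def _sample_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-sample metadata: label, age group, sex, site, severity score."""
    rows = []
    blocks = [
        ("case", "adult", config.n_adult_case),
        ("case", "pediatric", config.n_ped_case),
        ("control", "adult", config.n_adult_control),
        ("control", "pediatric", config.n_ped_control),
    ]
    i_case = i_ctrl = 0
    for label, age, n in blocks:
        for _ in range(n):
            if label == "case":
                i_case += 1
                sid = f"LS{i_case:02d}"
            else:
                i_ctrl += 1
                sid = f"HC{i_ctrl:02d}"
            rows.append((sid, label, age))
    meta = pd.DataFrame(rows, columns=["sample_id", "label", "age_group"]).set_index("sample_id")
    # female-skewed sex distribution, as in autoimmune skin disease cohorts
    meta["sex"] = rng.choice(list(config.sex_labels), size=len(meta), p=[0.62, 0.38])
    meta["site_group"] = rng.choice(list(config.site_labels), size=len(meta))
    sev = rng.integers(2, 35, size=len(meta)).astype(float)
    meta["severity_score"] = np.where(meta["label"] == "case", sev, 0.0)
    return meta


def _gene_panel(config: CohortConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    names = [
        f"G{c:02d}-{g:02d}"
        for c in range(config.n_clusters)
        for g in range(config.genes_per_cluster_pool)
    ]
    mito = [f"MT-G{i:02d}" for i in range(_N_MITO)]
    ribo = [f"RP-G{i:02d}" for i in range(_N_RIBO)]
    all_names = names + mito + ribo
    is_mito = np.zeros(len(all_names), dtype=bool)
    is_mito[len(names) : len(names) + _N_MITO] = True
    is_ribo = np.zeros(len(all_names), dtype=bool)
    is_ribo[len(names) + _N_MITO :] = True
    return all_names, is_mito, is_ribo


def _repair_cell(counts: np.ndarray, is_mito: np.ndarray, is_ribo: np.ndarray,
                 qc: QCThresholds, rng: np.random.Generator) -> None:
    """Clamp a non-violator cell inside the QC bounds, in place."""
    total = counts.sum()
    if total == 0:
        counts[rng.integers(0, len(counts))] = 1
        total = 1
    # cap mito / ribo fractions below their bounds with margin
    for mask, cap in ((is_mito, 0.8 * qc.max_mito), (is_ribo, 0.8 * qc.max_ribo)):
        sub = counts[mask].sum()
        if sub / counts.sum() >= cap:
            target = int(np.floor(cap * (counts.sum() - sub) / (1 - cap)))
            scale = target / max(sub, 1)
            counts[mask] = np.floor(counts[mask] * scale).astype(counts.dtype)
    # raise detected genes strictly above the floor
    detected = int((counts > 0).sum())
    need = qc.min_genes + 1 - detected
    if need > 0:
        zeros = np.flatnonzero(counts == 0)
        if len(zeros) < need:
            raise ValueError(
                "gene panel too small to satisfy min_genes; pass thresholds "
                "scaled to the panel size"
            )
        counts[rng.choice(zeros, size=need, replace=False)] = 1
    # lower detected genes strictly below the ceiling
    detected = int((counts > 0).sum())
    if detected >= qc.max_genes:
        nz = np.flatnonzero(counts > 0)
        drop = detected - qc.max_genes + 1
        counts[rng.choice(nz, size=drop, replace=False)] = 0


def _violate_cell(counts: np.ndarray, is_mito: np.ndarray, is_ribo: np.ndarray,
                  qc: QCThresholds, rng: np.random.Generator) -> None:
    """Force a cell outside at least one QC bound, in place."""
    mode = rng.choice(["low_genes", "high_mito", "high_ribo"])
    if mode == "low_genes":
        nz = np.flatnonzero(counts > 0)
        keep = min(len(nz), max(1, qc.min_genes // 2))
        drop = rng.permutation(nz)[keep:]
        counts[drop] = 0
    elif mode == "high_mito":
        other = counts[~is_mito].sum()
        frac = min(1.2 * qc.max_mito, 0.9)
        counts[is_mito] = 0
        counts[np.flatnonzero(is_mito)[0]] = int(np.ceil(frac * other / (1 - frac))) + 1
    else:
        other = counts[~is_ribo].sum()
        frac = min(1.1 * qc.max_ribo, 0.9)
        counts[is_ribo] = 0
        counts[np.flatnonzero(is_ribo)[0]] = int(np.ceil(frac * other / (1 - frac))) + 1


def simulate_cells(config: CohortConfig, qc: QCThresholds | None = None) -> ad.AnnData:
    """Draw a cohort of single cells with cluster structure and QC metrics.

    Counts follow a gamma-Poisson (negative binomial) model with a fixed
    per-gene dispersion, cluster-specific mean profiles (each cluster
    up-regulates its own gene block), and per-(sample, cluster) mean
    perturbations shared by all cells of a sample — the cell-level analogue
    of sample-level pseudobulk variation. A ``qc_violation_rate`` fraction of
    cells is pushed outside the QC bounds given by ``qc`` (default: study
    thresholds); all remaining cells are guaranteed inside those bounds.

    Returns an AnnData with sparse integer counts; ``.obs`` carries
    ``sample_id``, ``cluster``, ``n_detected_genes``, ``mito_fraction``,
    ``ribo_fraction`` and the planted ``qc_violator`` flag;
    ``.uns["samples"]`` holds the per-sample metadata table.
    """
    qc = qc or QCThresholds()
    rng = np.random.default_rng(config.seed)
    meta = _sample_table(config, rng)
    gene_names, is_mito, is_ribo = _gene_panel(config)
    n_genes = len(gene_names)
    pool = config.genes_per_cluster_pool

    # base relative expression per gene; cluster blocks get boosted in-cluster
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base[is_mito] = base[is_mito] * 0.5
    base[is_ribo] = base[is_ribo] * 1.0
    cluster_labels = [f"cluster{c:02d}" for c in range(config.n_clusters)]

    lo, hi = config.cells_per_sample
    phi = config.nb_dispersion
    target_depth = 2000.0

    blocks: list[sp.csr_matrix] = []
    obs_rows: list[dict] = []
    for sid in meta.index:
        n_cells = int(rng.integers(lo, hi + 1))
        props = rng.dirichlet(np.full(config.n_clusters, 5.0))
        cl = rng.choice(config.n_clusters, size=n_cells, p=props)
        # shared per-(sample, cluster) perturbation of the cluster's own block
        perturb = rng.lognormal(0.0, 0.4, size=(config.n_clusters, pool))
        lib = rng.lognormal(0.0, 0.3, size=n_cells)

        mu = np.tile(base, (n_cells, 1))
        for c in range(config.n_clusters):
            idx = cl == c
            if not idx.any():
                continue
            block = slice(c * pool, (c + 1) * pool)
            mu[np.ix_(idx, np.arange(*block.indices(n_genes)))] *= 4.0 * perturb[c]
        # scale to target depth (mito ~ a few %, ribo ~ 10-20% by construction)
        mu *= (target_depth * lib / mu.sum(axis=1))[:, None]

        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        counts = rng.poisson(lam).astype(np.int64)

        violator = rng.random(n_cells) < config.qc_violation_rate
        for i in range(n_cells):
            if violator[i]:
                _violate_cell(counts[i], is_mito, is_ribo, qc, rng)
            else:
                _repair_cell(counts[i], is_mito, is_ribo, qc, rng)

        totals = counts.sum(axis=1).astype(float)
        totals[totals == 0] = 1.0
        for i in range(n_cells):
            obs_rows.append(
                {
                    "sample_id": sid,
                    "cluster": cluster_labels[cl[i]],
                    "n_detected_genes": int((counts[i] > 0).sum()),
                    "mito_fraction": counts[i][is_mito].sum() / totals[i],
                    "ribo_fraction": counts[i][is_ribo].sum() / totals[i],
                    "qc_violator": bool(violator[i]),
                }
            )
        blocks.append(sp.csr_matrix(counts))

    X = sp.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i:06d}" for i in range(len(obs))]
    adata = ad.AnnData(
        X=X,
        obs=obs,
        var=pd.DataFrame({"mito": is_mito, "ribo": is_ribo}, index=gene_names),
    )
    adata.uns["samples"] = meta
    adata.uns["qc_thresholds"] = asdict(qc)
    logger.info("simulate_cells: %d cells x %d genes, %d samples", adata.n_obs, adata.n_vars, len(meta))
    return adata


def _build_weight_matrix(
    p: int, K: int, overlap_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Sparse overlapping allocation: norm-1 rows, >=2 pure features/factor.

    Features are split into K contiguous blocks (primary factor); the first
    two features of every block never overlap. An ``overlap_frac`` fraction
    of the remaining features additionally loads on a second factor, with
    both loadings 1/sqrt(2); signs are random so modules mix directions.
    """
    A = np.zeros((p, K))
    primary = (np.arange(p) * K) // p
    signs = rng.choice([-1.0, 1.0], size=p)
    A[np.arange(p), primary] = signs

    reserved = np.zeros(p, dtype=bool)
    for k in range(K):
        members = np.flatnonzero(primary == k)
        reserved[members[:2]] = True

    eligible = np.flatnonzero(~reserved)
    n_overlap = int(np.floor(overlap_frac * p))
    n_overlap = min(n_overlap, len(eligible))
    chosen = rng.choice(eligible, size=n_overlap, replace=False)
    for j in chosen:
        others = [k for k in range(K) if k != primary[j]]
        second = int(rng.choice(others))
        A[j, primary[j]] = signs[j] / np.sqrt(2.0)
        A[j, second] = rng.choice([-1.0, 1.0]) / np.sqrt(2.0)
    return A


def plant_pseudobulk(
    config: CohortConfig,
    K: int = 20,
    overlap_frac: float = 0.1,
    snr: float = 5.0,
    response_kind: str = "binary",
    n_signal: int = 5,
    effect_size: float = 3.0,
    response_noise_sd: float = 1.0,
) -> tuple[PseudobulkMatrix, pd.Series, PlantedTruth]:
    """Generate a pseudobulk matrix from a planted overlapping factor model.

    X = Z A' + E with Z ~ N(0, I) factor scores, A the sparse overlapping
    weight matrix (norm-1 rows), and E iid N(0, 1/snr^2); hence
    Cov(X) = A A' + sigma^2 I with sigma = 1/snr. The response is driven by
    ``n_signal`` randomly chosen factors with coefficient magnitude
    ``effect_size``: logistic-Bernoulli for ``binary``, linear plus
    N(0, response_noise_sd^2) noise for ``continuous``.

    For the binary kind the sample table's ``label`` column is set from the
    drawn response (case = 1) so downstream designs see a coherent cohort;
    for the continuous kind the response is stored as ``severity_score``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if snr <= 0:
        raise ValueError("snr must be positive")
    if response_kind not in ("binary", "continuous"):
        raise ValueError("response_kind must be 'binary' or 'continuous'")
    p = config.n_features
    if 2 * K > p:
        raise ValueError(f"K={K} too large for {p} features (need >= 2 pure features per factor)")

    rng = np.random.default_rng(config.seed)
    meta = _sample_table(config, rng)
    n = config.n_samples

    A = _build_weight_matrix(p, K, overlap_frac, rng)
    sigma = 1.0 / snr
    Z = rng.standard_normal((n, K))
    E = rng.standard_normal((n, p)) * sigma
    X = Z @ A.T + E

    factor_names = [f"F{k + 1:02d}" for k in range(K)]
    n_signal = min(n_signal, K)
    signal_idx = np.sort(rng.choice(K, size=n_signal, replace=False))
    beta = np.zeros(K)
    beta[signal_idx] = effect_size * rng.choice([-1.0, 1.0], size=n_signal)

    eta = Z @ beta
    if response_kind == "binary":
        y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(int)
        meta = meta.copy()
        meta["label"] = np.where(y == 1, "case", "control")
    else:
        y = eta + rng.standard_normal(n) * response_noise_sd
        meta = meta.copy()
        meta["severity_score"] = y

    feature_names = [
        f"cluster{c:02d}:G{c:02d}-{g:02d}"
        for c in range(config.n_clusters)
        for g in range(config.genes_per_cluster_pool)
    ]
    values = pd.DataFrame(X, index=meta.index, columns=feature_names)
    y_series = pd.Series(y, index=meta.index, name="response")
    truth = PlantedTruth(
        weight_matrix_true=pd.DataFrame(A, index=feature_names, columns=factor_names),
        factor_scores_true=pd.DataFrame(Z, index=meta.index, columns=factor_names),
        beta_true=pd.Series(beta, index=factor_names),
        noise_sd=sigma,
        signal_factor_ids=[factor_names[i] for i in signal_idx],
        response_kind=response_kind,
    )
    pb = PseudobulkMatrix(values=values, sample_meta=meta)
    return pb, y_series, truth


def simulate_transfer_cohort(
    truth: PlantedTruth,
    config: CohortConfig,
    feature_dropout: float = 0.1,
    shift: float = 0.0,
) -> tuple[PseudobulkMatrix, pd.Series]:
    """Draw a second cohort from the same planted truth, minus some features.

    A fresh cohort (sizes and seed from ``config``) is sampled from the same
    weight matrix, noise level and response coefficients; then
    ``floor(feature_dropout * p)`` randomly chosen features are removed and
    an optional constant ``shift`` is added to every retained feature —
    emulating an external cohort sharing most but not all of the feature
    space. Retained feature names are a subset of the reference's.
    """
    if not 0.0 <= feature_dropout < 1.0:
        raise ValueError("feature_dropout must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    meta = _sample_table(config, rng)
    n = len(meta)
    meta.index = ["X" + s for s in meta.index]  # distinct sample namespace

    A = truth.weight_matrix_true.to_numpy()
    p, K = A.shape
    Z = rng.standard_normal((n, K))
    X = Z @ A.T + rng.standard_normal((n, p)) * truth.noise_sd

    n_drop = int(np.floor(feature_dropout * p))
    keep = np.sort(rng.choice(p, size=p - n_drop, replace=False))
    features = [truth.feature_names[j] for j in keep]
    X = X[:, keep] + shift

    beta = truth.beta_true.to_numpy()
    eta = Z @ beta
    if truth.response_kind == "binary":
        y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(int)
        meta["label"] = np.where(y == 1, "case", "control")
    else:
        y = eta + rng.standard_normal(n) * 1.0
        meta["severity_score"] = y

    values = pd.DataFrame(X, index=meta.index, columns=features)
    return (
        PseudobulkMatrix(values=values, sample_meta=meta),
        pd.Series(y, index=meta.index, name="response"),
    )
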