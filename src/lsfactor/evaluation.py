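"""Cross-validation, permutation nulls, grouped holdout, and cohort transfer.

All held-out metrics are computed by re-running the full pipeline
(standardization -> factor estimation -> knockoff selection -> response
fit) strictly inside each training split; test samples only ever pass
through the frozen projection and coefficients. Binary designs are scored
by AUC, continuous designs by Spearman rho.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as adlib
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, spearmanr
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .factors import (
    LatentModel,
    ResponseFit,
    compute_loadings,
    estimate_latent_factors,
    fit_response,
    predict_response,
)
from .preprocess import PseudobulkMatrix
from .significance import KnockoffSelection, discover_interactions, gaussian_knockoffs, select_significant

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineSpec",
    "PipelineFit",
    "CVReport",
    "CrossPredictionResult",
    "compute_auc",
    "fit_pipeline",
    "predict_pipeline",
    "kfold_cv",
    "permutation_null",
    "grouped_cv",
    "transfer_clusters",
    "cross_predict",
    "factor_similarity",
]


@dataclass(frozen=True)
class PipelineSpec:
    """Hyperparameters of one factor-regression pipeline run.

    ``use_knockoffs=True`` restricts the response fit to knockoff-selected
    factors; when the selection comes back empty the fit falls back to all
    factors (logged) so held-out predictions are always defined.
    """

    task: str = "binary"  # "binary" | "continuous"
    delta: float = 0.1
    lam: float | None = None
    q: float = 0.05
    use_knockoffs: bool = True
    interactions: bool = False


@dataclass
class PipelineFit:
    """A pipeline fitted on one training matrix (standardization included)."""

    spec: PipelineSpec
    mu: pd.Series
    sd: pd.Series
    model: LatentModel
    selection: KnockoffSelection | None
    response_fit: ResponseFit


@dataclass
class CVReport:
    """Repeated k-fold cross-validation outcome (optionally with a null)."""

    metric_name: str
    metrics: list[float]  # one pooled out-of-fold metric per repeat
    fold_assignments: list[list[np.ndarray]]  # per repeat, per fold test indices
    k: int
    n_repeats: int
    seed: int
    null_metrics: list[float] = field(default_factory=list)
    p_value: float | None = None

    def to_json(self, path) -> None:
        payload = {
            "metric_name": self.metric_name,
            "metrics": self.metrics,
            "null_metrics": self.null_metrics,
            "p_value": self.p_value,
            "k": self.k,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class CrossPredictionResult:
    """Outcome of projecting a frozen model onto an external cohort."""

    predictions: pd.Series
    y_true: pd.Series
    metric_name: str
    metric: float
    metric_p: float | None
    matched_features: list[str]
    dropped_from_model: list[str]
    dropped_from_query: list[str]
    factor_cosines: list[tuple[str, str, float]]


def compute_auc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative (ties 0.5)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _raw_frame(X) -> tuple[pd.DataFrame, bool]:
    if isinstance(X, PseudobulkMatrix):
        return X.values, X.standardized
    return pd.DataFrame(X), False


def _standardize_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    sd = df.std(axis=0, ddof=1)
    keep = sd > 0
    df = df.loc[:, keep]
    mu = df.mean(axis=0)
    sd = sd[keep]
    return (df - mu) / sd, mu, sd


def fit_pipeline(X, y, spec: PipelineSpec = PipelineSpec(), seed: int = 0) -> PipelineFit:
    """Standardize, estimate factors, select, and fit the response."""
    df, already_std = _raw_frame(X)
    if already_std:
        Xs, mu, sd = df, pd.Series(0.0, index=df.columns), pd.Series(1.0, index=df.columns)
    else:
        Xs, mu, sd = _standardize_frame(df)
    model = estimate_latent_factors(Xs, delta=spec.delta, lam=spec.lam)
    Z = compute_loadings(model, Xs)

    selection = None
    terms: list = list(model.factor_names)
    if spec.use_knockoffs:
        Zk = gaussian_knockoffs(Z.scores, seed=seed)
        selection = select_significant(Z.scores, Zk, y, q=spec.q, seed=seed)
        if spec.interactions:
            selection = discover_interactions(selection, Z.scores, y, seed=seed)
        if selection.selected_marginal or selection.selected_interactions:
            terms = list(selection.selected_marginal) + list(selection.selected_interactions)
        else:
            logger.info("fit_pipeline: empty knockoff selection; falling back to all factors")
    fit = fit_response(Z, y, task=spec.task, terms=terms)
    model.response_fit = fit
    return PipelineFit(spec=spec, mu=mu, sd=sd, model=model, selection=selection, response_fit=fit)


def predict_pipeline(fit: PipelineFit, X) -> pd.Series:
    """Project new samples through a fitted pipeline's frozen parameters."""
    df, _ = _raw_frame(X)
    Xs = (df[fit.mu.index] - fit.mu) / fit.sd
    Z = compute_loadings(fit.model, Xs)
    return predict_response(fit.response_fit, Z)


def _metric(spec: PipelineSpec, y_true, preds) -> float:
    if spec.task == "binary":
        return compute_auc(preds, y_true)
    rho = spearmanr(np.asarray(y_true, dtype=float), np.asarray(preds, dtype=float)).statistic
    return float(rho)


def _one_cv_round(df, y_arr, spec, k, fold_seed) -> tuple[float, list[np.ndarray]]:
    n = len(y_arr)
    if spec.task == "binary":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        split_iter = splitter.split(np.zeros(n), y_arr.astype(int))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=fold_seed)
        split_iter = splitter.split(np.zeros(n))

    preds = np.empty(n, dtype=float)
    test_sets = []
    for f, (tr, te) in enumerate(split_iter):
        if spec.task == "binary" and len(np.unique(y_arr[tr])) < 2:
            raise RuntimeError("training fold lost a class")  # re-drawn by caller
        bundle = fit_pipeline(df.iloc[tr], y_arr[tr], spec, seed=fold_seed * 101 + f)
        preds[te] = predict_pipeline(bundle, df.iloc[te]).to_numpy()
        test_sets.append(te)
    return _metric(spec, y_arr, preds), test_sets


def kfold_cv(
    X,
    y,
    k: int = 5,
    n_repeats: int = 10,
    spec: PipelineSpec = PipelineSpec(),
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold CV of the full pipeline.

    The factor model and knockoff selection are refit inside every training
    fold; the per-repeat metric pools the out-of-fold predictions. Folds
    that would lose a class under stratification are re-drawn (logged).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df, _ = _raw_frame(X)
    y_arr = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    metrics, assignments = [], []
    for rep in range(n_repeats):
        for attempt in range(20):
            fold_seed = int(rng.integers(0, 2**31 - 1))
            try:
                m, test_sets = _one_cv_round(df, y_arr, spec, k, fold_seed)
                break
            except RuntimeError:
                logger.warning("kfold_cv: re-drawing folds (class missing), repeat %d", rep)
        else:
            raise ValueError("could not build folds with both classes in every training set")
        metrics.append(m)
        assignments.append(test_sets)
    name = "auc" if spec.task == "binary" else "spearman_rho"
    return CVReport(
        metric_name=name, metrics=metrics, fold_assignments=assignments,
        k=k, n_repeats=n_repeats, seed=seed,
    )


def permutation_null(
    X,
    y,
    k: int = 5,
    n_repeats: int = 10,
    n_perms: int = 20,
    spec: PipelineSpec = PipelineSpec(),
    seed: int = 0,
) -> CVReport:
    """Compare real CV performance against label-shuffled nulls.

    Each permutation shuffles the labels once and runs a single CV round;
    real and null metric distributions are compared by a one-sided
    Wilcoxon rank-sum test (real > null).
    """
    real = kfold_cv(X, y, k=k, n_repeats=n_repeats, spec=spec, seed=seed)
    df, _ = _raw_frame(X)
    y_arr = np.asarray(y, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))

    null_metrics = []
    for perm in range(n_perms):
        y_perm = rng.permutation(y_arr)
        for attempt in range(20):
            fold_seed = int(rng.integers(0, 2**31 - 1))
            try:
                m, _ = _one_cv_round(df, y_perm, spec, k, fold_seed)
                break
            except RuntimeError:
                continue
        else:
            raise ValueError("could not build folds for permuted labels")
        null_metrics.append(m)

    p = float(mannwhitneyu(real.metrics, null_metrics, alternative="greater").pvalue)
    return CVReport(
        metric_name=real.metric_name,
        metrics=real.metrics,
        fold_assignments=real.fold_assignments,
        k=k,
        n_repeats=n_repeats,
        seed=seed,
        null_metrics=null_metrics,
        p_value=p,
    )


def grouped_cv(X, y, groups, spec: PipelineSpec = PipelineSpec(), seed: int = 0) -> dict:
    """Leave-one-group-out holdout (e.g. anatomical site: trunk vs extremity).

    For each group g the pipeline trains on every sample outside g and is
    scored on g; train and test never share a sample. Returns per-group
    metrics plus the index bookkeeping.
    """
    df, _ = _raw_frame(X)
    y_arr = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    uniq = sorted(pd.unique(groups))
    if len(uniq) < 2:
        raise ValueError("grouped_cv requires at least 2 distinct groups")

    out = {}
    for g in uniq:
        te = np.flatnonzero(groups == g)
        tr = np.flatnonzero(groups != g)
        entry = {"train_index": tr, "test_index": te, "metric": None}
        try:
            bundle = fit_pipeline(df.iloc[tr], y_arr[tr], spec, seed=seed)
            preds = predict_pipeline(bundle, df.iloc[te]).to_numpy()
            entry["metric"] = _metric(spec, y_arr[te], preds)
        except ValueError as err:
            logger.warning("grouped_cv: group %s not scorable (%s)", g, err)
        out[g] = entry
    return out


def transfer_clusters(reference: adlib.AnnData, query: adlib.AnnData) -> pd.Series:
    """Assign query cells to reference clusters by nearest centroid.

    Centroids are per-cluster means of normalized expression over the shared
    gene set; distance is Pearson-correlation distance. Assignments whose
    best and second-best centroid correlations differ by < 1e-3 are counted
    and reported in a warning (ambiguous transfers).
    """
    shared = [g for g in reference.var_names if g in set(query.var_names)]
    if not shared:
        raise ValueError("no shared genes between reference and query")

    ref_X = reference[:, shared].X
    ref_X = ref_X.toarray() if sp.issparse(ref_X) else np.asarray(ref_X, dtype=float)
    clusters = sorted(reference.obs["cluster"].astype(str).unique())
    centroids = np.vstack([
        ref_X[(reference.obs["cluster"].astype(str) == c).to_numpy()].mean(axis=0)
        for c in clusters
    ])

    q_X = query[:, shared].X
    q_X = q_X.toarray() if sp.issparse(q_X) else np.asarray(q_X, dtype=float)

    def _rows_z(M):
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (M - mu) / sd

    corr = _rows_z(q_X) @ _rows_z(centroids).T / len(shared)
    best = np.argmax(corr, axis=1)
    if corr.shape[1] > 1:
        part = np.partition(corr, -2, axis=1)
        ambiguous = (part[:, -1] - part[:, -2]) < 1e-3
        if ambiguous.any():
            logger.warning("transfer_clusters: %d ambiguous assignments (margin < 1e-3)", int(ambiguous.sum()))
    return pd.Series([clusters[b] for b in best], index=query.obs_names, name="cluster")


def factor_similarity(model_a: LatentModel, model_b: LatentModel) -> list[tuple[str, str, float]]:
    """Greedy one-to-one factor matching maximizing |cosine| of weight columns.

    Columns are compared on the models' shared feature namespace; returns
    ``(factor_a, factor_b, |cosine|)`` for each matched pair.
    """
    shared = [f for f in model_a.feature_names if f in set(model_b.feature_names)]
    if not shared:
        raise ValueError("models share no features")
    Wa = model_a.weight_matrix.loc[shared].to_numpy()
    Wb = model_b.weight_matrix.loc[shared].to_numpy()

    def _norm(W):
        nrm = np.linalg.norm(W, axis=0)
        nrm[nrm == 0] = 1.0
        return W / nrm

    C = np.abs(_norm(Wa).T @ _norm(Wb))
    pairs = []
    rows = set(range(C.shape[0]))
    cols = set(range(C.shape[1]))
    while rows and cols:
        i, j = max(((i, j) for i in rows for j in cols), key=lambda t: C[t])
        pairs.append((model_a.factor_names[i], model_b.factor_names[j], float(C[i, j])))
        rows.discard(i)
        cols.discard(j)
    return pairs


def cross_predict(
    model: LatentModel,
    response_fit: ResponseFit,
    query: PseudobulkMatrix,
    y_query,
    X_train: PseudobulkMatrix | None = None,
    y_train=None,
    refit: bool | None = None,
) -> CrossPredictionResult:
    """Evaluate a frozen model on an external cohort after feature matching.

    Features are matched by intersection; features missing from the query
    are removed from the model's feature space on both sides. For
    classification the original coefficients are applied directly to the
    restricted model. For regression transfer (``refit=True``, the default
    when the task is continuous and training data is supplied) the factor
    model is re-estimated on the feature-matched training matrix with
    identical hyperparameters before projection, and factor preservation is
    reported as matched |cosine| values against the original model.
    """
    qdf, q_std = _raw_frame(query)
    matched = [f for f in model.feature_names if f in set(qdf.columns)]
    if not matched:
        raise ValueError("no feature overlap between model and query cohort")
    dropped_model = [f for f in model.feature_names if f not in set(matched)]
    dropped_query = [f for f in qdf.columns if f not in set(matched)]

    if refit is None:
        refit = response_fit.task == "continuous" and X_train is not None
    if refit:
        if X_train is None or y_train is None:
            raise ValueError("refit requires the training matrix and response")
        tdf, t_std = _raw_frame(X_train)
        tsub = tdf[matched]
        if not t_std:
            tsub, _, _ = _standardize_frame(tsub)
        model_m = estimate_latent_factors(
            tsub,
            delta=model.hyperparams.get("delta", 0.1),
            lam=model.hyperparams.get("lambda"),
        )
        Zt = compute_loadings(model_m, tsub)
        fit_m = fit_response(Zt, y_train, task=response_fit.task, terms=list(model_m.factor_names))
    else:
        model_m = model.restrict(matched)
        fit_m = response_fit

    qsub = qdf[matched]
    if not q_std:
        qsub, _, _ = _standardize_frame(qsub)
        # features constant in the query drop out of standardization; restrict again
        if list(qsub.columns) != matched:
            matched = list(qsub.columns)
            model_m = model_m.restrict(matched)
    Zq = compute_loadings(model_m, qsub)
    preds = predict_response(fit_m, Zq)

    y_arr = np.asarray(y_query, dtype=float)
    if response_fit.task == "binary":
        metric_name, metric, metric_p = "auc", compute_auc(preds.to_numpy(), y_arr), None
    else:
        res = spearmanr(y_arr, preds.to_numpy())
        metric_name, metric, metric_p = "spearman_rho", float(res.statistic), float(res.pvalue)

    cosines = factor_similarity(model, model_m)
    return CrossPredictionResult(
        predictions=preds,
        y_true=pd.Series(y_arr, index=preds.index),
        metric_name=metric_name,
        metric=metric,
        metric_p=metric_p,
        matched_features=matched,
        dropped_from_model=dropped_model,
        dropped_from_query=dropped_query,
        factor_cosines=cosines,
    )
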