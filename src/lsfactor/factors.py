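"""Overlapping latent-factor estimation and response regression.

The estimator follows the pure-variable (anchor) paradigm for identifiable
overlapping factor models:

1. compute the feature correlation matrix R of the standardized pseudobulk
   matrix;
2. detect *pure* features — feature i is pure when its maximal absolute
   off-diagonal correlation M_i is attained inside a group of mutually
   correlated features (all pairwise |r| within ``delta`` of M_i), and
   M_i >= delta at all;
3. group pure features into sign-aligned clusters (one latent factor per
   cluster) and initialize factor scores as signed averages of the cluster's
   features;
4. allocate each remaining (mixed) feature by an L1-penalized regression of
   the feature on the pure-factor scores at penalty ``lambda`` — overlap
   arises whenever two or more loadings survive the penalty.

Factor scores exposed to downstream stages are always the least-squares
projection of the data onto the weight matrix (see
:func:`compute_loadings`), so projecting the training matrix reproduces the
scores used during fitting exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LogisticRegression

from .preprocess import PseudobulkMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LatentModel",
    "FactorLoadings",
    "ResponseFit",
    "estimate_latent_factors",
    "compute_loadings",
    "fit_response",
    "predict_response",
    "default_lambda",
]


def default_lambda(n: int, p: int) -> float:
    """Default L1 penalty for mixed-feature allocation: 0.5 * sqrt(log p / n)."""
    return 0.5 * np.sqrt(np.log(max(p, 2)) / n)


@dataclass
class LatentModel:
    """Fitted overlapping factor model.

    ``weight_matrix`` is features x K and sparse in the sense that pure
    features are nonzero in exactly one column (+-1 after sign alignment)
    and mixed features carry their surviving L1 loadings.
    """

    K: int
    weight_matrix: pd.DataFrame
    factor_names: list[str]
    hyperparams: dict
    pure_features: dict[str, list[str]]
    response_fit: "ResponseFit | None" = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.weight_matrix.index)

    @property
    def model_id(self) -> str:
        h = hashlib.sha1(np.ascontiguousarray(self.weight_matrix.to_numpy()).tobytes())
        return h.hexdigest()[:12]

    def restrict(self, features: list[str]) -> "LatentModel":
        """Subset the model to a feature list (order taken from the model)."""
        keep = [f for f in self.feature_names if f in set(features)]
        if not keep:
            raise ValueError("no overlap between model features and requested features")
        keep_set = set(keep)
        return LatentModel(
            K=self.K,
            weight_matrix=self.weight_matrix.loc[keep],
            factor_names=list(self.factor_names),
            hyperparams=dict(self.hyperparams),
            pure_features={k: [f for f in v if f in keep_set] for k, v in self.pure_features.items()},
            response_fit=self.response_fit,
        )

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.weight_matrix.to_csv(outdir / "weight_matrix.tsv", sep="\t")
        meta = {
            "K": self.K,
            "factor_names": self.factor_names,
            "hyperparams": self.hyperparams,
            "pure_features": self.pure_features,
        }
        with open(outdir / "model.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, outdir) -> "LatentModel":
        outdir = Path(outdir)
        W = pd.read_csv(outdir / "weight_matrix.tsv", sep="\t", index_col=0)
        with open(outdir / "model.json") as fh:
            meta = json.load(fh)
        return cls(
            K=meta["K"],
            weight_matrix=W,
            factor_names=meta["factor_names"],
            hyperparams=meta["hyperparams"],
            pure_features=meta["pure_features"],
        )


@dataclass
class FactorLoadings:
    """Per-sample factor scores obtained by projecting expression data."""

    scores: pd.DataFrame  # samples x K
    source_model: str = ""

    @property
    def sample_names(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class ResponseFit:
    """Regression of a response on factor scores (and optional interactions).

    ``terms`` lists factor names and/or factor-name pairs. Interaction
    columns are products of z-scored factor scores, z-scored again before
    fitting; the transform statistics are stored so prediction on new
    cohorts applies the training-scale transform.
    """

    task: str  # "binary" | "continuous"
    terms: list
    intercept: float
    coef: pd.Series
    fitted: pd.Series
    score_mu: pd.Series | None = None
    score_sd: pd.Series | None = None
    prod_mu: dict = field(default_factory=dict)
    prod_sd: dict = field(default_factory=dict)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, PseudobulkMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def estimate_latent_factors(X, delta: float = 0.1, lam: float | None = None) -> LatentModel:
    """Estimate an overlapping latent factor model from standardized data.

    Parameters
    ----------
    X
        Standardized pseudobulk matrix (samples x features). A
        :class:`PseudobulkMatrix` must carry ``standardized=True``.
    delta
        Pure-variable correlation tolerance: the width of the band below a
        feature's maximal absolute correlation within which its partner
        group must be mutually correlated. Also the floor below which a
        feature cannot anchor a factor.
    lam
        L1 penalty for allocating mixed features; defaults to
        ``0.5 * sqrt(log p / n)``.

    Raises
    ------
    ValueError
        If no pure-variable cluster is found ("no factors detected").
    """
    if isinstance(X, PseudobulkMatrix) and not X.standardized:
        raise ValueError("estimate_latent_factors expects a standardized matrix")
    Xdf = _as_frame(X)
    n, p = Xdf.shape
    if n < 10:
        raise ValueError(f"need at least 10 samples to estimate factors, got {n}")
    if lam is None:
        lam = default_lambda(n, p)

    Xv = Xdf.to_numpy(dtype=float)
    R = np.corrcoef(Xv, rowvar=False)
    absR = np.abs(R)
    np.fill_diagonal(absR, 0.0)
    M = absR.max(axis=1)

    # pure-variable detection
    pure = np.zeros(p, dtype=bool)
    groups: list[np.ndarray] = [np.empty(0, dtype=int)] * p
    for i in range(p):
        if M[i] < delta:
            continue
        g = np.flatnonzero(absR[i] >= M[i] - delta)
        members = np.concatenate([[i], g])
        sub = absR[np.ix_(members, members)]
        off = sub[~np.eye(len(members), dtype=bool)]
        if (off >= M[i] - delta).all():
            pure[i] = True
            groups[i] = g

    pure_idx = np.flatnonzero(pure)
    if len(pure_idx) == 0:
        raise ValueError("no factors detected; lower delta")

    # cluster pure variables: edge iff mutual group membership
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    pos = {j: a for a, j in enumerate(pure_idx)}
    rows, cols = [], []
    for i in pure_idx:
        for j in groups[i]:
            if pure[j] and i in groups[j]:
                rows.append(pos[i])
                cols.append(pos[j])
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(pure_idx), len(pure_idx))
    )
    n_comp, comp = connected_components(adj, directed=False)

    clusters = []
    for c in range(n_comp):
        members = pure_idx[comp == c]
        if len(members) >= 2:  # a factor needs a corroborating partner
            clusters.append(np.sort(members))
    if not clusters:
        raise ValueError("no factors detected; lower delta")
    clusters.sort(key=lambda m: m[0])
    K = len(clusters)
    factor_names = [f"LF{k + 1}" for k in range(K)]
    features = list(Xdf.columns)

    W = np.zeros((p, K))
    pure_map: dict[str, list[str]] = {}
    Z0 = np.zeros((n, K))
    for k, members in enumerate(clusters):
        anchor = members[0]
        signs = np.sign(R[anchor, members])
        signs[members == anchor] = 1.0
        W[members, k] = signs
        Z0[:, k] = (Xv[:, members] * signs).mean(axis=1)
        pure_map[factor_names[k]] = [features[j] for j in members]

    # mixed features: L1 allocation onto standardized pure-factor scores
    is_pure_member = np.zeros(p, dtype=bool)
    for members in clusters:
        is_pure_member[members] = True
    mixed = np.flatnonzero(~is_pure_member)
    if len(mixed) > 0:
        Z0s = (Z0 - Z0.mean(axis=0)) / Z0.std(axis=0, ddof=1)
        lasso = Lasso(alpha=lam, fit_intercept=False, max_iter=5000)
        lasso.fit(Z0s, Xv[:, mixed])
        coefs = np.atleast_2d(lasso.coef_)
        W[mixed, :] = coefs

    model = LatentModel(
        K=K,
        weight_matrix=pd.DataFrame(W, index=features, columns=factor_names),
        factor_names=factor_names,
        hyperparams={"delta": delta, "lambda": lam},
        pure_features=pure_map,
    )
    logger.info(
        "estimate_latent_factors: K=%d factors, %d pure / %d mixed features",
        K, int(is_pure_member.sum()), len(mixed),
    )
    return model


def compute_loadings(model: LatentModel, X) -> FactorLoadings:
    """Least-squares projection of samples onto the factor weight matrix.

    scores = X W (W'W)^-1, i.e. the per-sample least-squares solve of
    x ~ W z. Linear in X; projecting the training matrix reproduces the
    training scores exactly.
    """
    Xdf = _as_frame(X)
    if set(Xdf.columns) != set(model.feature_names):
        raise ValueError(
            "feature mismatch between data and model; match features first "
            "(see evaluation.cross_predict / LatentModel.restrict)"
        )
    Xv = Xdf[model.feature_names].to_numpy(dtype=float)
    W = model.weight_matrix.to_numpy()
    scores = Xv @ np.linalg.pinv(W).T
    return FactorLoadings(
        scores=pd.DataFrame(scores, index=Xdf.index, columns=model.factor_names),
        source_model=model.model_id,
    )


def _design(Z: pd.DataFrame, terms: list, stats: ResponseFit | None = None):
    """Build the regression design for marginal + interaction terms.

    When ``stats`` is given, its stored transform parameters are applied
    (prediction path); otherwise they are computed from ``Z`` (fit path).
    """
    if stats is None:
        mu = Z.mean(axis=0)
        sd = Z.std(axis=0, ddof=1).replace(0.0, 1.0)
    else:
        mu, sd = stats.score_mu, stats.score_sd
    Zs = (Z - mu) / sd

    cols, names = [], []
    prod_mu, prod_sd = {}, {}
    for t in terms:
        if isinstance(t, str):
            cols.append(Z[t].to_numpy(dtype=float))
            names.append(t)
        else:
            a, b = t
            prod = (Zs[a] * Zs[b]).to_numpy(dtype=float)
            key = f"{a}*{b}"
            if stats is None:
                pm, ps = prod.mean(), prod.std(ddof=1) or 1.0
                prod_mu[key], prod_sd[key] = pm, ps
            else:
                pm, ps = stats.prod_mu[key], stats.prod_sd[key]
            cols.append((prod - pm) / ps)
            names.append(key)
    D = np.column_stack(cols) if cols else np.empty((len(Z), 0))
    return D, names, mu, sd, prod_mu, prod_sd


def fit_response(Z, y, task: str = "binary", terms: list | None = None) -> ResponseFit:
    """Regress the response on the named factor (and interaction) terms.

    Continuous responses use ordinary least squares; binary responses use a
    ridge-stabilized logistic fit (L2 penalty of strength 1/n), which also
    covers perfectly separated data gracefully.
    """
    Zdf = Z.scores if isinstance(Z, FactorLoadings) else _as_frame(Z)
    y_arr = np.asarray(y, dtype=float)
    if len(y_arr) != len(Zdf):
        raise ValueError("response length does not match number of samples")
    if terms is None:
        terms = list(Zdf.columns)
    bad = [t for t in terms if isinstance(t, str) and t not in Zdf.columns]
    if bad:
        raise ValueError(f"unknown factor terms: {bad}")

    D, names, mu, sd, prod_mu, prod_sd = _design(Zdf, terms)
    index = Zdf.index

    if task == "continuous":
        design = np.column_stack([np.ones(len(D)), D])
        beta, *_ = np.linalg.lstsq(design, y_arr, rcond=None)
        intercept, coef = float(beta[0]), beta[1:]
        fitted = design @ beta
    elif task == "binary":
        yb = y_arr.astype(int)
        if len(np.unique(yb)) < 2:
            logger.warning("fit_response: single-class response; intercept-only fit")
            p1 = float(yb.mean())
            intercept = float(np.log(p1 / (1 - p1))) if 0 < p1 < 1 else (20.0 if p1 >= 1 else -20.0)
            coef = np.zeros(D.shape[1])
            fitted = np.full(len(yb), p1, dtype=float)
        else:
            clf = LogisticRegression(C=float(len(yb)), max_iter=2000)  # L2 ridge, strength 1/n
            clf.fit(D, yb)
            intercept = float(clf.intercept_[0])
            coef = clf.coef_[0]
            fitted = clf.predict_proba(D)[:, 1]
    else:
        raise ValueError("task must be 'binary' or 'continuous'")

    return ResponseFit(
        task=task,
        terms=list(terms),
        intercept=intercept,
        coef=pd.Series(coef, index=names),
        fitted=pd.Series(fitted, index=index),
        score_mu=mu,
        score_sd=sd,
        prod_mu=prod_mu,
        prod_sd=prod_sd,
    )


def predict_response(fit: ResponseFit, Z) -> pd.Series:
    """Apply a frozen response fit to new factor loadings."""
    Zdf = Z.scores if isinstance(Z, FactorLoadings) else _as_frame(Z)
    D, names, *_ = _design(Zdf, fit.terms, stats=fit)
    eta = fit.intercept + D @ fit.coef.reindex(names).to_numpy()
    if fit.task == "binary":
        eta = 1.0 / (1.0 + np.exp(-eta))
    return pd.Series(eta, index=Zdf.index)
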