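"""Knockoff-based selection of significant factors and interactions.

Second-order Gaussian knockoffs with the equicorrelated construction:
given factor scores Z with mean mu and covariance Sigma, the knockoff copy
Z~ satisfies (in second moments) Cov(Z~) = Sigma and
Cov(Z, Z~) = Sigma - diag(s), where on the correlation scale
s_j = min(2 * lambda_min(R), 1). The knockoff filter then selects terms
whose antisymmetric statistics W exceed the data-dependent threshold

    T = min { t : (offset + #{W_j <= -t}) / max(1, #{W_j >= t}) <= q },

at target FDR level q (default 0.05). ``offset=0`` (default) is the
original filter, which controls the modified FDR E[FP] / (E[S] + 1/q) and
can return small discovery sets; ``offset=1`` is knockoff+, which controls
the FDR proper but cannot return fewer than 1/q discoveries and therefore
abstains entirely when only a handful of factors carry signal.

Interaction discovery is hierarchical: candidate products are formed only
from factors with at least one selected marginal parent, the response is
residualized on the selected marginals, and the filter is re-run over the
candidate set with its own Gaussian knockoffs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf
from sklearn.linear_model import Lasso, lasso_path

from .factors import FactorLoadings

logger = logging.getLogger(__name__)

__all__ = [
    "KnockoffSelection",
    "gaussian_knockoffs",
    "select_significant",
    "discover_interactions",
]


@dataclass
class KnockoffSelection:
    """Result of the knockoff filter at target FDR ``q``.

    ``selected_marginal`` is exactly the set of terms with ``W >= threshold``.
    """

    q: float
    W_stats: pd.Series
    threshold: float
    selected_marginal: list[str]
    selected_interactions: list[tuple[str, str]] = field(default_factory=list)
    statistic: str = "lasso_signed_max"
    seed: int | None = None
    offset: int = 0
    W_interactions: pd.Series | None = None
    interaction_threshold: float | None = None

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = {
            "q": self.q,
            "threshold": self.threshold,
            "W_stats": self.W_stats.to_dict(),
            "selected_marginal": self.selected_marginal,
            "selected_interactions": [list(t) for t in self.selected_interactions],
            "statistic": self.statistic,
            "seed": self.seed,
            "offset": self.offset,
        }
        with open(outdir / "selection.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        rows = [("marginal", t) for t in self.selected_marginal] + [
            ("interaction", f"{a}*{b}") for a, b in self.selected_interactions
        ]
        pd.DataFrame(rows, columns=["kind", "term"]).to_csv(
            outdir / "selected_terms.tsv", sep="\t", index=False
        )


def _scores_frame(Z) -> pd.DataFrame:
    if isinstance(Z, FactorLoadings):
        return Z.scores
    if isinstance(Z, pd.DataFrame):
        return Z
    arr = np.asarray(Z, dtype=float)
    return pd.DataFrame(arr, columns=[f"LF{j + 1}" for j in range(arr.shape[1])])


def gaussian_knockoffs(Z, seed: int = 0) -> pd.DataFrame:
    """Sample second-order Gaussian knockoffs of the factor scores.

    Deterministic given ``seed``. A near-singular sample covariance is
    shrunk toward its diagonal (logged) rather than failing silently.
    """
    Zdf = _scores_frame(Z)
    X = Zdf.to_numpy(dtype=float)
    n, K = X.shape
    if n <= K:
        logger.warning("gaussian_knockoffs: n=%d <= K=%d; sample covariance is singular", n, K)
    mu = X.mean(axis=0)
    # Ledoit-Wolf regularized covariance: at n >> K the shrinkage intensity
    # vanishes and this is the sample covariance; near n ~ K it keeps
    # lambda_min away from 0, without which s -> 0 and the knockoffs
    # degenerate into near-copies with no selection power
    lw = LedoitWolf().fit(X)
    if lw.shrinkage_ > 0.05:
        logger.info("gaussian_knockoffs: Ledoit-Wolf shrinkage %.3f", lw.shrinkage_)
    Sigma = lw.covariance_.reshape(K, K)

    d = np.sqrt(np.clip(np.diag(Sigma), 1e-12, None))
    Rcorr = Sigma / np.outer(d, d)
    lam_min = float(np.linalg.eigvalsh(Rcorr).min())
    if lam_min < 1e-6:
        gamma = 0.05
        logger.warning("gaussian_knockoffs: extra diagonal shrinkage (lambda_min=%.2e)", lam_min)
        Rcorr = (1 - gamma) * Rcorr + gamma * np.eye(K)
        Sigma = Rcorr * np.outer(d, d)
        lam_min = float(np.linalg.eigvalsh(Rcorr).min())

    s_corr = min(2.0 * lam_min, 1.0)
    S = np.diag(s_corr * d**2)

    Sigma_inv = np.linalg.inv(Sigma)
    C = 2.0 * S - S @ Sigma_inv @ S
    C = (C + C.T) / 2.0
    # eigenvalue square root, clipping tiny negatives from the boundary case
    w, V = np.linalg.eigh(C)
    Chalf = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T

    # dedicated stream: a seed shared with the data generator must not
    # replay the very draws that produced Z
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1201]))
    mean = mu + (X - mu) @ (np.eye(K) - Sigma_inv @ S)
    Zt = mean + rng.standard_normal((n, K)) @ Chalf
    return pd.DataFrame(Zt, index=Zdf.index, columns=[f"{c}~" for c in Zdf.columns])


def _entry_lambdas(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Largest penalty at which each column enters the lasso path."""
    n, p = A.shape
    alpha_max = np.abs(A.T @ y).max() / n
    if alpha_max <= 0:
        return np.zeros(p)
    alphas = alpha_max * np.logspace(0, -3, 100)
    _, coefs, _ = lasso_path(A, y, alphas=alphas)
    entered = np.abs(coefs) > 1e-10  # p x n_alphas, alphas decreasing
    entry = np.zeros(p)
    for j in range(p):
        hits = np.flatnonzero(entered[j])
        if len(hits) > 0:
            entry[j] = alphas[hits[0]]
    return entry


def _knockoff_threshold(W: np.ndarray, q: float, offset: int = 0) -> float:
    """Data-dependent knockoff threshold.

    ``offset=1`` gives the knockoff+ rule (strict FDR control); ``offset=0``
    gives the original filter (modified-FDR control). With a small number of
    candidate terms m the + rule is vacuous — it cannot return fewer than
    1/q discoveries — so the default here is the original rule.
    """
    candidates = np.sort(np.unique(np.abs(W[W != 0])))
    for t in candidates:
        fdp = (offset + np.sum(W <= -t)) / max(1, int(np.sum(W >= t)))
        if fdp <= q:
            return float(t)
    return np.inf


def select_significant(
    Z,
    Z_knock,
    y,
    q: float = 0.05,
    statistic: str = "lasso_signed_max",
    seed: int | None = None,
    offset: int = 0,
) -> KnockoffSelection:
    """Run the knockoff+ filter over factors at target FDR ``q``.

    ``lasso_signed_max`` (default) scores each term by the penalty at which
    it first enters the lasso path on the augmented [Z, Z~] design, signed
    by whether the real column or its knockoff enters first. ``coef_diff``
    uses |b_j| - |b~_j| from a single lasso fit. An empty selection is a
    valid outcome. ``offset=1`` switches to the knockoff+ rule.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    Zdf = _scores_frame(Z)
    Zkdf = _scores_frame(Z_knock)
    if Zdf.shape != Zkdf.shape:
        raise ValueError("factor scores and knockoffs must have matching shapes")
    terms = list(Zdf.columns)
    K = len(terms)

    A = np.column_stack([Zdf.to_numpy(dtype=float), Zkdf.to_numpy(dtype=float)])
    A = (A - A.mean(axis=0)) / np.where(A.std(axis=0, ddof=1) > 0, A.std(axis=0, ddof=1), 1.0)
    y_arr = np.asarray(y, dtype=float)
    y_c = y_arr - y_arr.mean()

    if statistic == "lasso_signed_max":
        entry = _entry_lambdas(A, y_c)
        lam_real, lam_ko = entry[:K], entry[K:]
        W = np.maximum(lam_real, lam_ko) * np.sign(lam_real - lam_ko)
    elif statistic == "coef_diff":
        n = len(y_c)
        lasso = Lasso(alpha=0.5 * np.sqrt(np.log(2 * K) / n), fit_intercept=False, max_iter=5000)
        lasso.fit(A, y_c)
        b = lasso.coef_
        W = np.abs(b[:K]) - np.abs(b[K:])
    else:
        raise ValueError("statistic must be 'lasso_signed_max' or 'coef_diff'")

    T = _knockoff_threshold(W, q, offset=offset)
    selected = [terms[j] for j in range(K) if W[j] >= T]
    logger.info("select_significant: %d / %d terms at q=%.3g", len(selected), K, q)
    return KnockoffSelection(
        q=q,
        W_stats=pd.Series(W, index=terms),
        threshold=T,
        selected_marginal=selected,
        statistic=statistic,
        seed=seed,
        offset=offset,
    )


def discover_interactions(
    selection: KnockoffSelection,
    Z,
    y,
    q: float | None = None,
    seed: int = 0,
) -> KnockoffSelection:
    """Knockoff-filter factor-pair interactions under a marginal hierarchy.

    Candidates are products of each selected marginal factor with every
    other factor (z-scored scores, product z-scored again). The response is
    first residualized on the selected marginals, then the filter is re-run
    over the candidate set with fresh Gaussian knockoffs. With no selected
    marginals the candidate set is empty and the selection is returned
    unchanged.
    """
    q = selection.q if q is None else q
    if not selection.selected_marginal:
        return selection

    Zdf = _scores_frame(Z)
    terms = list(Zdf.columns)
    Zs = (Zdf - Zdf.mean(axis=0)) / Zdf.std(axis=0, ddof=1).replace(0.0, 1.0)

    pairs: list[tuple[str, str]] = []
    seen = set()
    for a in selection.selected_marginal:
        for b in terms:
            if b == a:
                continue
            key = tuple(sorted((a, b)))
            if key not in seen:
                seen.add(key)
                pairs.append(key)

    C = pd.DataFrame(
        {f"{a}*{b}": Zs[a] * Zs[b] for a, b in pairs}, index=Zdf.index
    )
    sd = C.std(axis=0, ddof=1).replace(0.0, 1.0)
    C = (C - C.mean(axis=0)) / sd

    # residualize y on intercept + selected marginal scores
    y_arr = np.asarray(y, dtype=float)
    D = np.column_stack([np.ones(len(y_arr)), Zdf[selection.selected_marginal].to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(D, y_arr, rcond=None)
    y_resid = y_arr - D @ beta

    C_knock = gaussian_knockoffs(C, seed=seed)
    inner = select_significant(
        C, C_knock, y_resid, q=q, statistic=selection.statistic, seed=seed,
        offset=selection.offset,
    )
    chosen = [pairs[i] for i, name in enumerate(C.columns) if name in set(inner.selected_marginal)]
    logger.info("discover_interactions: %d / %d candidate pairs selected", len(chosen), len(pairs))
    return KnockoffSelection(
        q=selection.q,
        W_stats=selection.W_stats,
        threshold=selection.threshold,
        selected_marginal=list(selection.selected_marginal),
        selected_interactions=chosen,
        statistic=selection.statistic,
        seed=selection.seed,
        offset=selection.offset,
        W_interactions=inner.W_stats,
        interaction_threshold=inner.threshold,
    )
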