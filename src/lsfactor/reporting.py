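"""Interpretable outputs per significant latent factor.

For each selected factor the reportable unit is a set of *nodes* —
cluster-gene features chosen either for their contribution to the factor's
composition (top-|weight|) or for univariate predictiveness of the response
— plus a signed correlation network over those nodes thresholded at
|r| > 0.25, mirroring the convention of coloring positive edges purple and
negative edges green, with triangles/squares encoded as an ``up_in_case`` /
``up_in_control`` direction attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .factors import LatentModel, compute_loadings
from .preprocess import PseudobulkMatrix
from .significance import KnockoffSelection

logger = logging.getLogger(__name__)

__all__ = ["FactorNetwork", "top_genes", "correlation_network", "factor_summary"]

EDGE_CUTOFF_DEFAULT = 0.25


@dataclass
class FactorNetwork:
    """Signed correlation network over a factor's top features.

    Every edge satisfies |correlation| > ``cutoff``; the edge ``sign``
    equals the sign of the correlation and the ``color`` attribute follows
    the purple (+) / green (-) convention.
    """

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            (u, v, d["correlation"], d["sign"], d["color"])
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["feature_a", "feature_b", "correlation", "sign", "color"])

    def save(self, outdir, name: str = "network") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(self.graph, outdir / f"{name}.graphml")
        self.edges.to_csv(outdir / f"{name}_edges.tsv", sep="\t", index=False)
        nodes = pd.DataFrame(
            [{"feature": n, **d} for n, d in self.graph.nodes(data=True)]
        )
        nodes.to_csv(outdir / f"{name}_nodes.tsv", sep="\t", index=False)


def _feature_response_assoc(x: np.ndarray, y: np.ndarray, binary: bool) -> float:
    """Univariate association: point-biserial (binary) or Spearman (continuous)."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    if binary:
        return float(np.corrcoef(x, y)[0, 1])
    return float(spearmanr(x, y).statistic)


def _is_binary(y: np.ndarray) -> bool:
    return len(np.unique(y)) == 2


def top_genes(model: LatentModel, factor: str, X, y, n: int = 10) -> pd.DataFrame:
    """Union of top-n loading features and top-n response-predictive features.

    Both rankings run over the factor's nonzero-weight support; the
    ``basis`` column records whether a node entered by loading magnitude,
    predictiveness, or both, and ``direction`` carries the sign of the
    gene-response association (``up_in_case`` / ``up_in_control``).
    A factor with fewer than ``n`` nonzero weights contributes them all.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if factor not in model.factor_names:
        raise ValueError(f"unknown factor {factor!r}")
    Xdf = X.values if isinstance(X, PseudobulkMatrix) else pd.DataFrame(X)
    y_arr = np.asarray(y, dtype=float)
    binary = _is_binary(y_arr)

    col = model.weight_matrix[factor]
    support = col[col != 0.0]
    if len(support) < n:
        logger.info("top_genes: factor %s has only %d nonzero weights", factor, len(support))

    by_weight = sorted(support.index, key=lambda f: (-abs(support[f]), f))[:n]
    assoc = {
        f: _feature_response_assoc(Xdf[f].to_numpy(dtype=float), y_arr, binary)
        for f in support.index
    }
    by_assoc = sorted(support.index, key=lambda f: (-abs(assoc[f]), f))[:n]

    rows = []
    for f in sorted(set(by_weight) | set(by_assoc), key=lambda f: (-abs(support[f]), f)):
        basis = (
            "both" if f in set(by_weight) and f in set(by_assoc)
            else "loading" if f in set(by_weight)
            else "predictive"
        )
        cluster = f.split(":", 1)[0] if ":" in f else ""
        direction = "up_in_case" if assoc[f] >= 0 else "up_in_control"
        rows.append(
            {
                "feature": f,
                "cluster": cluster,
                "weight": float(support[f]),
                "association": assoc[f],
                "direction": direction,
                "basis": basis,
            }
        )
    return pd.DataFrame(rows)


def correlation_network(nodes, X, cutoff: float = EDGE_CUTOFF_DEFAULT) -> FactorNetwork:
    """Pearson-correlation network over node features, |r| > cutoff.

    ``nodes`` is a ``top_genes`` table or a list of feature names. Constant
    features cannot carry a correlation and are excluded with a warning.
    """
    if isinstance(nodes, pd.DataFrame):
        node_attrs = {r["feature"]: r.drop(labels=["feature"]).to_dict() for _, r in nodes.iterrows()}
        names = list(nodes["feature"])
    else:
        names = list(nodes)
        node_attrs = {f: {} for f in names}
    if len(names) < 2:
        raise ValueError("correlation_network requires at least 2 nodes")
    Xdf = X.values if isinstance(X, PseudobulkMatrix) else pd.DataFrame(X)

    usable = []
    for f in names:
        if Xdf[f].std(ddof=1) == 0:
            logger.warning("correlation_network: excluding constant feature %s", f)
        else:
            usable.append(f)

    G = nx.Graph()
    for f in usable:
        G.add_node(f, **{k: v for k, v in node_attrs[f].items() if v is not None})
    for a, b in combinations(usable, 2):
        r = float(np.corrcoef(Xdf[a].to_numpy(dtype=float), Xdf[b].to_numpy(dtype=float))[0, 1])
        if abs(r) > cutoff:
            G.add_edge(a, b, correlation=r, sign=int(np.sign(r)), color="purple" if r > 0 else "green")
    return FactorNetwork(graph=G, cutoff=cutoff)


def factor_summary(
    model: LatentModel,
    selection: KnockoffSelection,
    X,
    y,
    n_top: int = 10,
) -> dict:
    """Numeric backing table per selected factor.

    For each selected factor: the per-sample factor score, the factor-level
    response association (AUC for binary, Spearman rho for continuous), and
    per-group mean expression of the factor's top genes.
    """
    if not selection.selected_marginal:
        raise ValueError("factor_summary requires a non-empty selection")
    Xpb = X if isinstance(X, PseudobulkMatrix) else PseudobulkMatrix(values=pd.DataFrame(X))
    y_arr = np.asarray(y, dtype=float)
    binary = _is_binary(y_arr)
    loadings = compute_loadings(model, Xpb.values).scores

    out = {}
    for factor in selection.selected_marginal:
        score = loadings[factor]
        if binary:
            from .evaluation import compute_auc

            assoc = compute_auc(score.to_numpy(), y_arr.astype(int))
            groups = {"case": y_arr == 1, "control": y_arr == 0}
        else:
            assoc = float(spearmanr(score.to_numpy(), y_arr).statistic)
            med = np.median(y_arr)
            groups = {"high_severity": y_arr > med, "low_severity": y_arr <= med}

        nodes = top_genes(model, factor, Xpb, y, n=n_top)
        means = {
            g: Xpb.values.loc[mask, nodes["feature"]].mean(axis=0).to_dict()
            for g, mask in groups.items()
        }
        out[factor] = {
            "scores": score,
            "association": assoc,
            "top_genes": nodes,
            "group_means": means,
        }
    return out
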