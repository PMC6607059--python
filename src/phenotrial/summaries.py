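"""Descriptive trait summaries and Pearson correlation networks.

Summaries (mean, sd, CV, percent reduction versus control) are computed
per trait and treatment.  Correlation networks are built, one treatment
at a time, from the Pearson correlation matrix of genotype-level values
(normally BLUPs): traits are nodes, significant correlations are signed,
weighted edges whose width is proportional to |r|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

__all__ = [
    "summarize_traits",
    "correlation_matrix",
    "build_network",
    "CorrelationNetwork",
]


def summarize_traits(
    table: pd.DataFrame, control: str = "C"
) -> pd.DataFrame:
    """Per trait x treatment: mean, sd, CV (%) and percent reduction.

    Works on replicate-level trait tables or long BLUP tables (any long
    table with trait/treatment/value columns and >= 2 values per group).
    CV = 100 * sd / mean with the sample (n-1) standard deviation.
    percent_reduction = 100 * (mean_control - mean) / mean_control; it is
    undefined (``reduction_defined = False``) when the control mean is
    zero or the treatment is the control itself.
    """
    grouped = table.groupby(["trait", "treatment"], sort=False)["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size").reset_index()
    if (out["n"] < 2).any():
        raise ValueError("need >= 2 values per trait x treatment")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["cv_percent"] = 100.0 * out["sd"] / np.abs(out["mean"])
    out.loc[out["sd"] == 0, "cv_percent"] = 0.0

    ctrl = out[out["treatment"] == control].set_index("trait")["mean"]
    if ctrl.empty:
        raise ValueError(f"control treatment {control!r} not present")
    ctrl_mean = out["trait"].map(ctrl)
    defined = (out["treatment"] != control) & (ctrl_mean != 0) & ctrl_mean.notna()
    reduction = 100.0 * (ctrl_mean - out["mean"]) / ctrl_mean
    out["percent_reduction"] = reduction.where(defined)
    out["reduction_defined"] = defined
    return out.drop(columns="n")


def correlation_matrix(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations and two-sided p-values between trait columns.

    ``values`` is a genotype x trait matrix (rows observations, columns
    traits), typically the BLUPs of one treatment.  p-values come from
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  Zero-variance
    traits give NaN correlations (their pairs are excluded from any
    network built on the result).
    """
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need >= 3 observations (genotypes)")
    sd = X.std(axis=0, ddof=1)
    Xc = X - X.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.outer(sd, sd) * (n - 1)
        r = (Xc.T @ Xc) / denom
    r[~np.isfinite(r)] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    good = sd > 0
    for i in range(p):
        r[i, i] = 1.0 if good[i] else np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    pmat = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pmat = np.where(np.isclose(np.abs(r), 1.0), 0.0, pmat)
    pmat = np.where(np.isnan(r), np.nan, pmat)
    np.fill_diagonal(pmat, 0.0)
    cols = list(values.columns)
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(pmat, index=cols, columns=cols),
    )


@dataclass
class CorrelationNetwork:
    """Signed, weighted trait-correlation network for one treatment."""

    nodes: list[str]
    categories: dict[str, str]
    edges: pd.DataFrame  # columns: trait_i, trait_j, r, p, sign, width
    alpha: float
    treatment: str | None = None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(alpha=self.alpha, treatment=self.treatment)
        for node in self.nodes:
            g.add_node(node, category=self.categories.get(node, "unknown"))
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.trait_i, row.trait_j,
                r=row.r, p=row.p, sign=row.sign, width=row.width,
            )
        return g

    def to_json(self, path) -> None:
        payload = {
            "treatment": self.treatment,
            "alpha": self.alpha,
            "nodes": [
                {"name": n, "category": self.categories.get(n, "unknown")}
                for n in self.nodes
            ],
            "edges": self.edges.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    alpha: float = 0.05,
    categories: dict[str, str] | None = None,
    holm: bool = False,
    treatment: str | None = None,
) -> CorrelationNetwork:
    """Threshold a correlation matrix into a network at significance alpha.

    Edges connect trait pairs with p < alpha; edge sign records the
    direction of the correlation and width = |r|.  ``holm`` applies a
    Holm step-down adjustment over the upper-triangle p-values before
    thresholding.  Node order (and hence edge order) follows the matrix
    columns, so output is deterministic.
    """
    nodes = list(r.columns)
    rm = r.to_numpy(float)
    pm = p.to_numpy(float).copy()
    iu = np.triu_indices(len(nodes), k=1)
    if holm:
        pv = pm[iu]
        finite = np.isfinite(pv)
        adj = pv.copy()
        order = np.argsort(pv[finite])
        m = finite.sum()
        ranked = pv[finite][order] * (m - np.arange(m))
        adj_sorted = np.maximum.accumulate(ranked)
        vals = np.minimum(adj_sorted, 1.0)
        tmp = np.empty(m)
        tmp[order] = vals
        adj[finite] = tmp
        pm[iu] = adj
        pm.T[iu] = adj

    rows = []
    for a, b in zip(*iu):
        pv = pm[a, b]
        rv = rm[a, b]
        if np.isfinite(pv) and np.isfinite(rv) and pv < alpha:
            rows.append(
                {
                    "trait_i": nodes[a],
                    "trait_j": nodes[b],
                    "r": rv,
                    "p": pv,
                    "sign": int(np.sign(rv)) if rv != 0 else 0,
                    "width": abs(rv),
                }
            )
    edges = pd.DataFrame(
        rows, columns=["trait_i", "trait_j", "r", "p", "sign", "width"]
    )
    return CorrelationNetwork(
        nodes=nodes,
        categories=dict(categories or {}),
        edges=edges,
        alpha=alpha,
        treatment=treatment,
    )
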