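"""AMMI decomposition of a genotype x treatment two-way table.

Additive main effects are removed by double-centering,

    tg_ij = y_ij - ybar_i. - ybar_.j + ybar_.. ,

and the interaction matrix is decomposed by SVD into interaction
principal components (IPCs).  Genotype and treatment scores use
symmetric scaling (both sides multiplied by sqrt of the singular value),
so the inner product of a genotype and a treatment score vector over all
components reconstructs tg_ij.  A genotype's distance from the biplot
origin summarizes its interaction instability (0 = perfectly additive,
i.e. maximally stable across treatments).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AmmiResult", "double_center", "decompose", "stability_summary"]


def double_center(table: pd.DataFrame) -> pd.DataFrame:
    """Remove row and column main effects, keeping the interaction.

    ``table`` is a complete genotype x treatment matrix.  Every row and
    column of the result sums to zero; the operation is idempotent and
    invariant to adding constants to any row or column of the input.
    """
    if table.isna().any().any():
        raise ValueError("two-way table has missing cells")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 genotypes and >= 2 treatments")
    Y = table.to_numpy(dtype=float)
    grand = Y.mean()
    inter = Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + grand
    return pd.DataFrame(inter, index=table.index, columns=table.columns)


@dataclass
class AmmiResult:
    """SVD of the interaction matrix with biplot coordinates."""

    interaction: pd.DataFrame
    singular_values: np.ndarray  # all min(G-1, T-1) values
    genotype_scores: pd.DataFrame  # IPC1..IPCk, symmetric scaling
    treatment_scores: pd.DataFrame
    variance_explained: np.ndarray  # percent, per retained component
    n_components: int

    @property
    def interaction_ss(self) -> float:
        return float((self.interaction.to_numpy() ** 2).sum())

    def to_json(self, path) -> None:
        payload = {
            "singular_values": [float(v) for v in self.singular_values],
            "variance_explained_percent": [
                float(v) for v in self.variance_explained
            ],
            "interaction_ss": self.interaction_ss,
            "n_components": self.n_components,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    def scores_table(self) -> pd.DataFrame:
        """Long table of genotype and treatment biplot coordinates."""
        g = self.genotype_scores.copy()
        g.insert(0, "entity", "genotype")
        t = self.treatment_scores.copy()
        t.insert(0, "entity", "treatment")
        out = pd.concat([g, t])
        out.index.name = "name"
        return out.reset_index()[["entity", "name", *g.columns[1:]]]


def decompose(interaction: pd.DataFrame, n_components: int = 2) -> AmmiResult:
    """SVD the (double-centered) interaction matrix into IPC scores.

    Component k explains 100 * lambda_k^2 / sum(lambda^2) percent of the
    interaction sum of squares.  The sign of each component is fixed by
    making the largest-magnitude genotype loading positive, so results
    are reproducible across platforms.  An all-zero interaction yields
    zero scores and zero variance explained, with a warning.
    """
    Z = interaction.to_numpy(dtype=float)
    G, T = Z.shape
    rank = min(G - 1, T - 1)
    if rank < 1:
        raise ValueError("interaction matrix must be at least 2 x 2")
    n_components = min(n_components, rank)

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    s = s[:rank]
    U = U[:, :rank]
    Vt = Vt[:rank]

    for k in range(rank):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] *= -1.0
            Vt[k] *= -1.0

    ss = float(np.sum(s**2))
    if ss <= 0:
        warnings.warn(
            "interaction matrix is zero; AMMI components undefined", UserWarning
        )
        var_exp = np.zeros(n_components)
    else:
        var_exp = 100.0 * s[:n_components] ** 2 / ss

    scale = np.sqrt(s)
    cols = [f"IPC{k + 1}" for k in range(n_components)]
    g_scores = pd.DataFrame(
        U[:, :n_components] * scale[None, :n_components],
        index=interaction.index,
        columns=cols,
    )
    t_scores = pd.DataFrame(
        Vt[:n_components].T * scale[None, :n_components],
        index=interaction.columns,
        columns=cols,
    )
    return AmmiResult(
        interaction=interaction,
        singular_values=s,
        genotype_scores=g_scores,
        treatment_scores=t_scores,
        variance_explained=var_exp,
        n_components=n_components,
    )


def stability_summary(result: AmmiResult) -> pd.DataFrame:
    """Per-genotype interaction stability from the biplot geometry.

    ``distance`` is the Euclidean norm of the genotype's IPC score
    vector (smaller = more stable across treatments).  ``cos_<t>`` is
    the cosine of the angle between the genotype's and treatment t's
    score vectors: positive when the genotype's interaction pattern
    favors that treatment, near zero when unrelated.
    """
    if result.n_components < 2:
        raise ValueError("stability summary needs >= 2 components")
    Gs = result.genotype_scores.to_numpy(dtype=float)
    Ts = result.treatment_scores.to_numpy(dtype=float)
    dist = np.linalg.norm(Gs, axis=1)
    out = pd.DataFrame(
        {"distance": dist}, index=result.genotype_scores.index
    )
    t_norm = np.linalg.norm(Ts, axis=1)
    for j, treatment in enumerate(result.treatment_scores.index):
        denom = dist * t_norm[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            cosine = (Gs @ Ts[j]) / denom
        out[f"cos_{treatment}"] = np.where(denom > 0, cosine, 0.0)
    out.index.name = "genotype"
    return out
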