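"""Shared fixtures and independent dense-matrix oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenotrial import SimConfig


def make_trait_table(values: np.ndarray, treatments=None, trait="y") -> pd.DataFrame:
    """Long trait table from a (G, T, R) value cube."""
    values = np.asarray(values, dtype=float)
    G, T, R = values.shape
    treatments = list(treatments) if treatments is not None else [
        f"T{j + 1}" for j in range(T)
    ]
    rows = []
    for g in range(G):
        for t in range(T):
            for r in range(R):
                rows.append(
                    {
                        "genotype": f"G{g + 1:02d}",
                        "treatment": treatments[t],
                        "replicate": r + 1,
                        "trait": trait,
                        "value": values[g, t, r],
                    }
                )
    return pd.DataFrame(rows)


def dense_mixed_model(data: pd.DataFrame, trait: str, variances: dict, s2e,
                      include_replicate_fixed: bool = True):
    """Brute-force GLS/BLUP solve with explicit n x n covariance matrices.

    Independent of the package's MME route: builds V = ZGZ' + R densely,
    computes the REML log-likelihood, GLS fixed effects and the BLUPs
    u_hat = G Z' V^{-1} (y - X beta_hat).
    """
    sub = data[data["trait"] == trait]
    y = sub["value"].to_numpy(float)
    n = y.size
    treatments = list(pd.unique(sub["treatment"]))
    genotypes = list(pd.unique(sub["genotype"]))
    replicates = list(pd.unique(sub["replicate"]))
    t = pd.Categorical(sub["treatment"], treatments).codes
    g = pd.Categorical(sub["genotype"], genotypes).codes
    r = pd.Categorical(sub["replicate"], replicates).codes
    T, G, R = len(treatments), len(genotypes), len(replicates)

    if include_replicate_fixed:
        X = np.zeros((n, R))
        X[:, 0] = 1.0
        for k in range(1, R):
            X[r == k, k] = 1.0
    else:
        X = np.ones((n, 1))
    ZT = np.eye(T)[t]
    ZG = np.eye(G)[g]
    ZGT = np.eye(G * T)[g * T + t]

    s2e_vec = np.atleast_1d(np.asarray(s2e, float))
    if s2e_vec.size == 1:
        s2e_vec = np.repeat(s2e_vec, T)
    Rm = np.diag(s2e_vec[t])
    V = (
        variances["treatment"] * ZT @ ZT.T
        + variances["genotype"] * ZG @ ZG.T
        + variances["gxt"] * ZGT @ ZGT.T
        + Rm
    )
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    yPy = float(resid @ Vi @ y)
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    p = X.shape[1]
    ll = -0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldX + yPy)

    uT = variances["treatment"] * ZT.T @ Vi @ resid
    uG = variances["genotype"] * ZG.T @ Vi @ resid
    uGT = (variances["gxt"] * ZGT.T @ Vi @ resid).reshape(G, T)
    mu = float(beta[0]) + (float(beta[1:].sum()) / R if include_replicate_fixed else 0.0)
    pred = mu + uT[None, :] + uG[:, None] + uGT
    return {
        "logREML": ll,
        "beta": beta,
        "u_treatment": uT,
        "u_genotype": uG,
        "u_gxt": uGT,
        "predictions": pred,
        "genotypes": genotypes,
        "treatments": treatments,
    }


@pytest.fixture
def small_sim() -> SimConfig:
    """Compact balanced trial for fast fitting tests."""
    return SimConfig(
        n_genotypes=8,
        n_reps=4,
        sigma2_G=2.0,
        sigma2_GT=0.5,
        sigma2_E=1.0,
        seed=11,
    )
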