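"""Variance components, REML, heritability and BLUPs for balanced trials.

Fits, one trait at a time, the Gaussian linear mixed model

    y = X beta + Z u + eps

where the fixed part X holds an intercept and (optionally) crossed
replicate effects, and the random part u stacks treatment, genotype and
genotype-by-treatment effects, each i.i.d. normal with its own variance
component.  Residuals are independent with either a single pooled
variance or one variance per treatment; the two residual models are
compared by AIC.  Estimation is REML via EM iterations on the
mixed-model equations (MME); for balanced data a method-of-moments
estimator from the ANOVA expected mean squares serves as a closed-form
cross-check.

Downstream stages consume the genotype-by-treatment BLUPs
mu + t_j + g_i + (gt)_ij predicted from the selected fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2, norm

logger = logging.getLogger("phenotrial")

__all__ = [
    "ModelSpec",
    "VarianceComponentFit",
    "MixedModelWorkspace",
    "fit_moments",
    "fit_reml",
    "select_residual_model",
    "lr_test_random",
    "heritability_and_contributions",
    "genotype_blups",
    "flag_outliers",
    "replicate_wald_test",
    "UnbalancedDataError",
]

RANDOM_TERMS = ("treatment", "genotype", "gxt")

#: lower bound on variance components, keeps G^{-1} finite at boundaries
VARIANCE_FLOOR = 1e-10


class UnbalancedDataError(ValueError):
    """Raised when an estimator requiring a balanced design gets unbalanced data."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a single-trait mixed-model fit.

    ``residual_model`` selects pooled ("homogeneous") or per-treatment
    ("heterogeneous") residual variances.  ``random_terms`` defaults to
    the full model (treatment, genotype, genotype x treatment); reduced
    models for likelihood-ratio tests drop terms from this tuple.
    ``tol`` is the convergence tolerance on successive restricted
    log-likelihood values.
    """

    trait_name: str
    residual_model: str = "homogeneous"
    include_replicate_fixed: bool = True
    random_terms: tuple[str, ...] = RANDOM_TERMS
    max_iter: int = 500
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.residual_model not in ("homogeneous", "heterogeneous"):
            raise ValueError("residual_model must be homogeneous|heterogeneous")
        unknown = set(self.random_terms) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class VarianceComponentFit:
    """Estimated variance components and fit metadata for one trait."""

    trait: str
    residual_model: str
    treatments: tuple[str, ...]
    sigma2_T: float
    sigma2_G: float
    sigma2_GT: float
    sigma2_E: float | np.ndarray
    logREML: float
    n_params: int
    AIC: float
    converged: bool
    n_iter: int
    method: str
    random_terms: tuple[str, ...] = RANDOM_TERMS
    include_replicate_fixed: bool = True
    boundary: tuple[str, ...] = ()
    n_obs: int = 0

    def residual_by_treatment(self) -> np.ndarray:
        s2e = np.atleast_1d(np.asarray(self.sigma2_E, dtype=float))
        if s2e.size == 1:
            s2e = np.repeat(s2e, len(self.treatments))
        return s2e

    def residual_mean(self) -> float:
        """Unweighted mean of per-treatment residual variances."""
        return float(self.residual_by_treatment().mean())

    def components(self) -> dict[str, float]:
        return {
            "treatment": self.sigma2_T,
            "genotype": self.sigma2_G,
            "gxt": self.sigma2_GT,
            "error": self.residual_mean(),
        }

    def to_dict(self) -> dict:
        d = {
            "trait": self.trait,
            "residual_model": self.residual_model,
            "treatments": list(self.treatments),
            "sigma2_T": self.sigma2_T,
            "sigma2_G": self.sigma2_G,
            "sigma2_GT": self.sigma2_GT,
            "sigma2_E": (
                float(self.sigma2_E)
                if np.isscalar(self.sigma2_E) or np.ndim(self.sigma2_E) == 0
                else [float(v) for v in np.asarray(self.sigma2_E)]
            ),
            "logREML": self.logREML,
            "n_params": self.n_params,
            "AIC": self.AIC,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "method": self.method,
            "boundary": list(self.boundary),
            "n_obs": self.n_obs,
        }
        return d


# ---------------------------------------------------------------------------
# design / workspace


def _extract_trait(data: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = data[data["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in data")
    return sub.reset_index(drop=True)


class MixedModelWorkspace:
    """Precomputed design quantities for fast repeated REML evaluation.

    Builds the stacked design ``W = [X | Z]`` and caches the per-treatment
    Gram blocks ``W_j' W_j``, ``W_j' y_j`` and ``y_j' y_j`` so that every
    evaluation of the restricted likelihood, every EM update and the MME
    solve are small dense-matrix operations independent of n.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        sub = _extract_trait(data, spec.trait_name)
        self.spec = spec
        self.y = sub["value"].to_numpy(dtype=float)
        self.n = self.y.size

        self.treatments = tuple(pd.unique(sub["treatment"]))
        self.genotypes = tuple(pd.unique(sub["genotype"]))
        self.replicates = tuple(pd.unique(sub["replicate"]))
        self.T = len(self.treatments)
        self.G = len(self.genotypes)
        self.R = len(self.replicates)
        if self.G < 2:
            raise ValueError("need >= 2 genotypes")
        if self.T < 2:
            raise ValueError("need >= 2 treatments")
        if self.R < 2:
            raise ValueError("need >= 2 replicates")

        t_idx = pd.Categorical(sub["treatment"], categories=self.treatments).codes
        g_idx = pd.Categorical(sub["genotype"], categories=self.genotypes).codes
        r_idx = pd.Categorical(sub["replicate"], categories=self.replicates).codes
        self.t_idx = np.asarray(t_idx)

        # fixed part: intercept + reference-coded replicate dummies
        if spec.include_replicate_fixed:
            X = np.zeros((self.n, self.R))
            X[:, 0] = 1.0
            for k in range(1, self.R):
                X[r_idx == k, k] = 1.0
        else:
            X = np.ones((self.n, 1))
        self.p = X.shape[1]

        # random part: one indicator block per active term
        blocks: list[np.ndarray] = []
        self.block_slices: dict[str, slice] = {}
        start = self.p
        for term in spec.random_terms:
            if term == "treatment":
                q, codes = self.T, t_idx
            elif term == "genotype":
                q, codes = self.G, g_idx
            else:
                q, codes = self.G * self.T, g_idx * self.T + t_idx
            Zb = np.zeros((self.n, q))
            Zb[np.arange(self.n), codes] = 1.0
            blocks.append(Zb)
            self.block_slices[term] = slice(start, start + q)
            start += q
        self.q = start - self.p
        self.W = np.hstack([X] + blocks)
        m = self.p + self.q

        # per-treatment sufficient statistics
        self.M = np.zeros((self.T, m, m))
        self.b = np.zeros((self.T, m))
        self.s = np.zeros(self.T)
        self.n_by_t = np.zeros(self.T, dtype=int)
        for j in range(self.T):
            rows = self.t_idx == j
            Wj = self.W[rows]
            yj = self.y[rows]
            self.M[j] = Wj.T @ Wj
            self.b[j] = Wj.T @ yj
            self.s[j] = yj @ yj
            self.n_by_t[j] = rows.sum()

    # -- parameter handling --------------------------------------------------

    def _ginv_diag(self, variances: dict[str, float]) -> np.ndarray:
        d = np.zeros(self.p + self.q)
        for term, sl in self.block_slices.items():
            d[sl] = 1.0 / max(variances[term], VARIANCE_FLOOR)
        return d

    def _assemble(self, variances: dict[str, float], s2e: np.ndarray):
        w = 1.0 / np.maximum(s2e, VARIANCE_FLOOR)
        C = np.tensordot(w, self.M, axes=1)
        rhs = w @ self.b
        yRy = float(w @ self.s)
        C[np.diag_indices_from(C)] += self._ginv_diag(variances)
        return C, rhs, yRy

    def reml_pieces(self, variances: dict[str, float], s2e: np.ndarray):
        """Cholesky of the MME matrix, solution, and -2 logREML."""
        s2e = np.maximum(np.asarray(s2e, dtype=float), VARIANCE_FLOOR)
        C, rhs, yRy = self._assemble(variances, s2e)
        cho = linalg.cho_factor(C, lower=True, check_finite=False)
        theta = linalg.cho_solve(cho, rhs, check_finite=False)
        yPy = yRy - float(rhs @ theta)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        logdet_R = float(self.n_by_t @ np.log(s2e))
        logdet_G = sum(
            (sl.stop - sl.start) * np.log(max(variances[t], VARIANCE_FLOOR))
            for t, sl in self.block_slices.items()
        )
        neg2 = (
            (self.n - self.p) * np.log(2.0 * np.pi)
            + logdet_R
            + logdet_G
            + logdet_C
            + yPy
        )
        return cho, theta, -0.5 * neg2

    def logREML(self, variances: dict[str, float], s2e) -> float:
        s2e = np.atleast_1d(np.asarray(s2e, dtype=float))
        if s2e.size == 1:
            s2e = np.repeat(s2e, self.T)
        return self.reml_pieces(variances, s2e)[2]

    # -- REML estimation -----------------------------------------------------

    def _estep(self, variances: dict[str, float], s2e: np.ndarray):
        """MME solve plus the E-step expectations used by EM and scoring.

        Returns the restricted log-likelihood, the EM updates for every
        variance parameter, and the expected sums of squares that also
        yield the analytic REML score.
        """
        s2e_c = np.maximum(s2e, VARIANCE_FLOOR)
        C, rhs, yRy = self._assemble(variances, s2e_c)
        cho = linalg.cho_factor(C, lower=True, check_finite=False)
        theta = linalg.cho_solve(cho, rhs, check_finite=False)
        Cinv = linalg.cho_solve(cho, np.eye(self.p + self.q), check_finite=False)
        yPy = yRy - float(rhs @ theta)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        logdet_R = float(self.n_by_t @ np.log(s2e_c))
        logdet_G = sum(
            (sl.stop - sl.start) * np.log(max(variances[t], VARIANCE_FLOOR))
            for t, sl in self.block_slices.items()
        )
        ll = -0.5 * (
            (self.n - self.p) * np.log(2.0 * np.pi)
            + logdet_R
            + logdet_G
            + logdet_C
            + yPy
        )

        uu = {}
        tr_cbb = {}
        for term, sl in self.block_slices.items():
            u = theta[sl]
            uu[term] = float(u @ u)
            tr_cbb[term] = float(np.trace(Cinv[sl, sl]))
        ee = np.empty(self.T)
        tr_cm = np.empty(self.T)
        for j in range(self.T):
            ee[j] = (
                self.s[j]
                - 2.0 * float(self.b[j] @ theta)
                + float(theta @ self.M[j] @ theta)
            )
            tr_cm[j] = float(np.sum(Cinv * self.M[j]))
        return ll, uu, tr_cbb, ee, tr_cm

    def _score_log(self, variances, s2e, uu, tr_cbb, ee, tr_cm, het: bool):
        """Gradient of -2 logREML with respect to the log-variances.

        Uses tr(P V_b) = (q_b - tr(C^bb)/s2_b)/s2_b and
        y'P V_b P y = u_b'u_b / s2_b^2 (and their residual analogues), so
        the score comes for free from the E-step quantities.
        """
        grad = []
        for term, sl in self.block_slices.items():
            s2 = max(variances[term], VARIANCE_FLOOR)
            q_b = sl.stop - sl.start
            d = (q_b - tr_cbb[term] / s2) / s2 - uu[term] / s2**2
            grad.append(d * s2)  # chain rule onto log scale
        s2e_c = np.maximum(s2e, VARIANCE_FLOOR)
        d_res = (self.n_by_t - tr_cm / s2e_c) / s2e_c - ee / s2e_c**2
        if het:
            grad.extend(d_res * s2e_c)
        else:
            grad.append(float(np.sum(d_res)) * s2e_c[0])
        return np.asarray(grad)

    def em_fit(self, residual_model: str, max_iter: int, tol: float):
        """REML by EM warm-up plus analytic-gradient quasi-Newton polish.

        EM updates on the mixed-model equations increase the restricted
        log-likelihood monotonically and are run until its change falls
        below ``tol`` (or a warm-up cap); a bounded L-BFGS pass on the
        log-variances with the exact REML score then sharpens the
        estimates to optimizer precision, which EM's linear tail
        convergence cannot reach near small components.
        """
        from scipy import optimize

        het = residual_model == "heterogeneous"
        v_tot = float(np.var(self.y))
        if v_tot <= 0:
            v_tot = 1.0
        k = len(self.block_slices) + 1
        variances = {t: v_tot / k for t in self.block_slices}
        s2e = np.full(self.T, v_tot / k)
        terms = list(self.block_slices)

        prev = -np.inf
        converged = False
        ll = -np.inf
        warmup = min(max_iter, 200)
        it = 0
        for it in range(1, warmup + 1):
            ll, uu, tr_cbb, ee, tr_cm = self._estep(variances, s2e)
            new_var = {
                term: (uu[term] + tr_cbb[term]) / (sl.stop - sl.start)
                for term, sl in self.block_slices.items()
            }
            ess = ee + tr_cm
            new_s2e = ess / self.n_by_t if het else np.full(self.T, ess.sum() / self.n)
            if np.isfinite(ll) and abs(ll - prev) < tol:
                converged = True
                variances, s2e = new_var, new_s2e
                break
            prev = ll
            variances, s2e = new_var, new_s2e

        # polish on the log scale with the analytic score
        n_res = self.T if het else 1
        x0 = np.log(
            np.maximum(
                np.array([variances[t] for t in terms] + list(s2e[:n_res])),
                VARIANCE_FLOOR,
            )
        )

        def unpack(x):
            v = {t: float(np.exp(x[i])) for i, t in enumerate(terms)}
            res = np.exp(x[len(terms):])
            s2 = res if het else np.full(self.T, float(res[0]))
            return v, s2

        def fun_grad(x):
            v, s2 = unpack(x)
            ll_x, uu, tr_cbb, ee, tr_cm = self._estep(v, s2)
            g = self._score_log(v, s2, uu, tr_cbb, ee, tr_cm, het)
            return -2.0 * ll_x, g

        res = optimize.minimize(
            fun_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(np.log(VARIANCE_FLOOR), np.log(1e8 * v_tot))] * x0.size,
            options={"maxiter": max(max_iter, 200), "ftol": 1e-18, "gtol": 1e-12},
        )
        x = np.asarray(res.x, dtype=float)
        converged = converged or bool(res.success)
        n_iter = it + int(res.nit)

        # Newton polish on the score: the objective itself is too noisy
        # (Cholesky round-off ~1e-11) for line searches to resolve the
        # last ~1e-5 of the optimum, but the analytic gradient is clean,
        # so solve grad = 0 directly for interior parameters.
        lb = np.log(VARIANCE_FLOOR)
        score_tol = max(1e-10, min(1e-5, 100.0 * tol))
        for _ in range(8):
            g = fun_grad(x)[1]
            free = (x > lb + 1.0) | (g < 0)
            if not free.any() or np.max(np.abs(g[free])) < score_tol:
                break
            idx = np.nonzero(free)[0]
            h = 1e-5
            J = np.empty((idx.size, idx.size))
            for a, ia in enumerate(idx):
                xp = x.copy()
                xp[ia] += h
                J[:, a] = (fun_grad(xp)[1][idx] - g[idx]) / h
            try:
                step = np.linalg.solve(J, g[idx])
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            step = np.clip(step, -1.0, 1.0)
            x_new = x.copy()
            x_new[idx] = np.clip(x[idx] - step, lb, np.log(1e8 * v_tot))
            g_new = fun_grad(x_new)[1]
            if np.max(np.abs(g_new[idx])) >= np.max(np.abs(g[idx])):
                break
            x = x_new
            n_iter += 1

        variances, s2e = unpack(x)
        ll = fun_grad(x)[0] * -0.5
        return variances, s2e, ll, converged, n_iter


# ---------------------------------------------------------------------------
# estimators


def _balanced_cube(sub: pd.DataFrame):
    """Reshape a balanced single-trait table to a (G, T, R) value cube."""
    piv = sub.pivot_table(
        index="genotype", columns=["treatment", "replicate"], values="value",
        aggfunc="first", sort=False,
    )
    if piv.isna().any().any():
        raise UnbalancedDataError(
            "design is not balanced/complete; use fit_reml for unbalanced data"
        )
    counts = sub.groupby(["genotype", "treatment"], sort=False).size()
    if counts.nunique() != 1:
        raise UnbalancedDataError(
            "unequal replication across cells; use fit_reml for unbalanced data"
        )
    genotypes = list(piv.index)
    treatments = list(dict.fromkeys(piv.columns.get_level_values(0)))
    replicates = sorted(set(piv.columns.get_level_values(1)))
    G, T, R = len(genotypes), len(treatments), len(replicates)
    cube = np.empty((G, T, R))
    for tj, t in enumerate(treatments):
        block = piv[t]
        cube[:, tj, :] = block[replicates].to_numpy(dtype=float)
    return cube, genotypes, treatments, replicates


def fit_moments(
    data: pd.DataFrame,
    trait: str,
    include_replicate_fixed: bool = True,
) -> VarianceComponentFit:
    """Closed-form ANOVA (expected-mean-squares) variance components.

    Balanced designs only.  Solves the EMS equations

        sigma2_G  = (MS_G - MS_GT) / (R * T)
        sigma2_GT = (MS_GT - MS_E) / R
        sigma2_T  = (MS_T - MS_GT) / (G * R)
        sigma2_E  = MS_E

    truncating negative solutions to zero (recorded in ``boundary``).
    With ``include_replicate_fixed`` the replicate sum of squares is
    removed from the error stratum (df (GT-1)(R-1)), matching the REML
    model with fixed crossed replication.  The restricted log-likelihood
    is evaluated at the resulting estimates so AIC is comparable with
    REML fits.
    """
    sub = _extract_trait(data, trait)
    cube, genotypes, treatments, replicates = _balanced_cube(sub)
    G, T, R = cube.shape
    if G < 2 or T < 2 or R < 2:
        raise ValueError("need >= 2 genotypes, treatments and replicates")

    grand = cube.mean()
    g_mean = cube.mean(axis=(1, 2))
    t_mean = cube.mean(axis=(0, 2))
    r_mean = cube.mean(axis=(0, 1))
    cell_mean = cube.mean(axis=2)

    ms_g = T * R * np.sum((g_mean - grand) ** 2) / (G - 1)
    ms_t = G * R * np.sum((t_mean - grand) ** 2) / (T - 1)
    inter = cell_mean - g_mean[:, None] - t_mean[None, :] + grand
    ms_gt = R * np.sum(inter**2) / ((G - 1) * (T - 1))
    ss_within = np.sum((cube - cell_mean[:, :, None]) ** 2)
    if include_replicate_fixed:
        ss_rep = G * T * np.sum((r_mean - grand) ** 2)
        df_e = (G * T - 1) * (R - 1)
        ms_e = (ss_within - ss_rep) / df_e
    else:
        ms_e = ss_within / (G * T * (R - 1))

    raw = {
        "error": ms_e,
        "gxt": (ms_gt - ms_e) / R,
        "genotype": (ms_g - ms_gt) / (R * T),
        "treatment": (ms_t - ms_gt) / (G * R),
    }
    boundary = tuple(k for k, v in raw.items() if v < 0)
    est = {k: max(v, 0.0) for k, v in raw.items()}

    spec = ModelSpec(
        trait_name=trait, include_replicate_fixed=include_replicate_fixed
    )
    ws = MixedModelWorkspace(sub, spec)
    variances = {
        "treatment": est["treatment"],
        "genotype": est["genotype"],
        "gxt": est["gxt"],
    }
    ll = ws.logREML(variances, est["error"])
    n_params = 4
    return VarianceComponentFit(
        trait=trait,
        residual_model="homogeneous",
        treatments=tuple(treatments),
        sigma2_T=est["treatment"],
        sigma2_G=est["genotype"],
        sigma2_GT=est["gxt"],
        sigma2_E=est["error"],
        logREML=float(ll),
        n_params=n_params,
        AIC=float(-2.0 * ll + 2 * n_params),
        converged=True,
        n_iter=0,
        method="moments",
        include_replicate_fixed=include_replicate_fixed,
        boundary=boundary,
        n_obs=int(cube.size),
    )


def fit_reml(data: pd.DataFrame, spec: ModelSpec) -> VarianceComponentFit:
    """REML variance components by EM iteration on the MME.

    Returns a fit with the restricted log-likelihood and
    AIC = -2 logREML + 2 n_params, where n_params counts the variance
    parameters of the chosen residual model.  Non-convergence within
    ``spec.max_iter`` returns the last iterate with ``converged=False``
    and a logged warning.
    """
    ws = MixedModelWorkspace(data, spec)
    variances, s2e, ll, converged, n_iter = ws.em_fit(
        spec.residual_model, spec.max_iter, spec.tol
    )
    if not converged:
        logger.warning(
            "REML did not converge for trait %r within %d iterations",
            spec.trait_name,
            spec.max_iter,
        )
    het = spec.residual_model == "heterogeneous"
    n_params = len(ws.block_slices) + (ws.T if het else 1)
    boundary = tuple(
        t for t, v in variances.items() if v <= 10 * VARIANCE_FLOOR
    )
    return VarianceComponentFit(
        trait=spec.trait_name,
        residual_model=spec.residual_model,
        treatments=ws.treatments,
        sigma2_T=float(variances.get("treatment", 0.0)),
        sigma2_G=float(variances.get("genotype", 0.0)),
        sigma2_GT=float(variances.get("gxt", 0.0)),
        sigma2_E=(np.asarray(s2e, float) if het else float(s2e[0])),
        logREML=float(ll),
        n_params=n_params,
        AIC=float(-2.0 * ll + 2 * n_params),
        converged=converged,
        n_iter=n_iter,
        method="reml",
        random_terms=spec.random_terms,
        include_replicate_fixed=spec.include_replicate_fixed,
        boundary=boundary,
        n_obs=ws.n,
    )


def select_residual_model(
    fit_hom: VarianceComponentFit, fit_het: VarianceComponentFit
) -> VarianceComponentFit:
    """Pick the residual model with the lower AIC (tie -> homogeneous)."""
    if fit_hom.trait != fit_het.trait or fit_hom.n_obs != fit_het.n_obs:
        raise ValueError("fits must come from the same trait and data")
    pair = sorted(
        (fit_hom, fit_het), key=lambda f: (f.AIC, f.residual_model != "homogeneous")
    )
    return pair[0]


def lr_test_random(
    fit_full: VarianceComponentFit, fit_reduced: VarianceComponentFit
) -> tuple[float, float]:
    """Likelihood-ratio test of a random term on the variance boundary.

    LR = 2 (logREML_full - logREML_reduced), clipped at zero.  Because
    the null value sits on the boundary of the parameter space, the
    reference distribution for one dropped term is the equal mixture
    (1/2) chi2_0 + (1/2) chi2_1; for d dropped terms the mixture
    (1/2)(chi2_{d-1} + chi2_d) is used.
    """
    if fit_full.trait != fit_reduced.trait:
        raise ValueError("fits must be for the same trait")
    if not set(fit_reduced.random_terms) < set(fit_full.random_terms):
        raise ValueError("models are not nested in their random terms")
    if fit_full.residual_model != fit_reduced.residual_model:
        raise ValueError("residual models differ; not a random-term comparison")
    d = len(fit_full.random_terms) - len(fit_reduced.random_terms)
    lr = max(0.0, 2.0 * (fit_full.logREML - fit_reduced.logREML))
    if lr == 0.0:
        return 0.0, 1.0
    lower = 0.0 if d == 1 else chi2.sf(lr, d - 1)
    p = 0.5 * (lower + chi2.sf(lr, d))
    return lr, float(p)


def heritability_and_contributions(
    fit: VarianceComponentFit,
) -> tuple[float, dict[str, float]]:
    """Sample-basis heritability and relative variance contributions.

    h2 = sigma2_G / (sigma2_G + sigma2_GT + sigma2_eps), with the
    residual entering as the unweighted mean across treatments when the
    heterogeneous model was selected.  Contribution shares additionally
    include the treatment component and sum to one.
    """
    comp = fit.components()
    total = sum(comp.values())
    if total <= 0:
        raise ValueError("all variance components are zero; h2 undefined")
    denom = comp["genotype"] + comp["gxt"] + comp["error"]
    h2 = 0.0 if denom == 0 else comp["genotype"] / denom
    shares = {k: v / total for k, v in comp.items()}
    return float(h2), shares


# ---------------------------------------------------------------------------
# predictions and diagnostics


def _solve_mme(data: pd.DataFrame, fit: VarianceComponentFit):
    spec = ModelSpec(
        trait_name=fit.trait,
        residual_model=fit.residual_model,
        include_replicate_fixed=fit.include_replicate_fixed,
        random_terms=fit.random_terms,
    )
    ws = MixedModelWorkspace(data, spec)
    variances = {
        "treatment": fit.sigma2_T,
        "genotype": fit.sigma2_G,
        "gxt": fit.sigma2_GT,
    }
    variances = {t: variances[t] for t in ws.block_slices}
    s2e = fit.residual_by_treatment()
    cho, theta, ll = ws.reml_pieces(variances, s2e)
    return ws, cho, theta


def genotype_blups(fit: VarianceComponentFit, data: pd.DataFrame) -> pd.DataFrame:
    """Predict genotype values per treatment from the mixed-model equations.

    Returns a long table (genotype, treatment, trait, value) with
    value = mu_hat + t_hat_j + g_hat_i + gt_hat_ij, where mu_hat is the
    fixed-effect prediction averaged over replicates.  Predictions
    shrink toward the treatment mean as the residual variance grows and
    converge to observed cell means as it vanishes.
    """
    ws, cho, theta = _solve_mme(data, fit)
    beta = theta[: ws.p]
    mu = float(beta[0]) + (float(beta[1:].sum()) / ws.R if ws.p > 1 else 0.0)

    t_eff = np.zeros(ws.T)
    g_eff = np.zeros(ws.G)
    gt_eff = np.zeros((ws.G, ws.T))
    if "treatment" in ws.block_slices:
        t_eff = theta[ws.block_slices["treatment"]]
    if "genotype" in ws.block_slices:
        g_eff = theta[ws.block_slices["genotype"]]
    if "gxt" in ws.block_slices:
        gt_eff = theta[ws.block_slices["gxt"]].reshape(ws.G, ws.T)

    values = mu + t_eff[None, :] + g_eff[:, None] + gt_eff
    idx = pd.MultiIndex.from_product(
        [list(ws.genotypes), list(ws.treatments)], names=["genotype", "treatment"]
    )
    out = pd.DataFrame({"trait": fit.trait, "value": values.reshape(-1)}, index=idx)
    return out.reset_index()[["genotype", "treatment", "trait", "value"]]


def blup_matrix(blups: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    """Pivot a long BLUP table into a genotype x treatment matrix."""
    sub = blups if trait is None else blups[blups["trait"] == trait]
    return sub.pivot_table(
        index="genotype", columns="treatment", values="value", sort=False,
        aggfunc="first",
    )


def flag_outliers(
    data: pd.DataFrame, fit: VarianceComponentFit, threshold: float = 3.0
) -> pd.DataFrame:
    """Flag observations with large studentized conditional residuals.

    Conditional residuals e = y - X beta_hat - Z u_hat are standardized
    by their exact prediction variances diag(R - W C^{-1} W') from the
    mixed-model equations.  Rows with |studentized| > threshold are
    returned (flagging only; nothing is removed).
    """
    ws, cho, theta = _solve_mme(data, fit)
    resid = ws.y - ws.W @ theta
    CinvWt = linalg.cho_solve(cho, ws.W.T, check_finite=False)
    leverage = np.einsum("ij,ji->i", ws.W, CinvWt)
    s2e = fit.residual_by_treatment()[ws.t_idx]
    var = np.maximum(s2e - leverage, 1e-12 * np.maximum(s2e, VARIANCE_FLOOR))
    stud = resid / np.sqrt(var)

    sub = _extract_trait(data, fit.trait).copy()
    sub["residual"] = resid
    sub["studentized"] = stud
    flagged = sub[np.abs(stud) > threshold]
    return flagged.reset_index(drop=True)


def replicate_wald_test(
    data: pd.DataFrame, fit: VarianceComponentFit
) -> pd.DataFrame:
    """Simple z-tests of the replicate fixed-effect contrasts.

    Each reference-coded replicate contrast beta_k is divided by its
    standard error from the inverse MME matrix; two-sided normal
    p-values.  (Small-sample df corrections are out of scope.)
    """
    if not fit.include_replicate_fixed:
        raise ValueError("fit has no replicate fixed effect")
    ws, cho, theta = _solve_mme(data, fit)
    Cinv = linalg.cho_solve(cho, np.eye(ws.p + ws.q), check_finite=False)
    rows = []
    for k in range(1, ws.p):
        est = float(theta[k])
        se = float(np.sqrt(Cinv[k, k]))
        z = est / se if se > 0 else 0.0
        rows.append(
            {
                "contrast": f"rep{ws.replicates[k]}-rep{ws.replicates[0]}",
                "estimate": est,
                "se": se,
                "z": z,
                "p": 2.0 * float(norm.sf(abs(z))),
            }
        )
    return pd.DataFrame(rows)
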