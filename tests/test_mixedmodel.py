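"""Variance components: ANOVA oracle, REML, BLUPs, h2, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from conftest import dense_mixed_model, make_trait_table

from phenotrial import (
    ModelSpec,
    SimConfig,
    UnbalancedDataError,
    VarianceComponentFit,
    fit_moments,
    fit_reml,
    flag_outliers,
    genotype_blups,
    blup_matrix,
    heritability_and_contributions,
    lr_test_random,
    replicate_wald_test,
    select_residual_model,
    simulate_trial,
)


def _fit(trait="y", **kw):
    defaults = dict(
        trait=trait, residual_model="homogeneous",
        treatments=("T1", "T2"), sigma2_T=0.0, sigma2_G=0.0, sigma2_GT=0.0,
        sigma2_E=0.0, logREML=0.0, n_params=4, AIC=0.0, converged=True,
        n_iter=1, method="reml", n_obs=8,
    )
    defaults.update(kw)
    return VarianceComponentFit(**defaults)


# ---------------------------------------------------------------------------
# method of moments


def test_moments_recovers_pure_genotype_variance():
    """Genotype effects (-1, 0, 1), T=2, R=2, no noise: MS_G=4 -> s2_G=1."""
    cube = np.zeros((3, 2, 2))
    for g, eff in enumerate((-1.0, 0.0, 1.0)):
        cube[g] = eff
    fit = fit_moments(make_trait_table(cube), "y")
    assert fit.sigma2_G == pytest.approx(1.0, abs=1e-12)
    assert fit.sigma2_GT == pytest.approx(0.0, abs=1e-12)
    assert fit.sigma2_E == pytest.approx(0.0, abs=1e-12)


def test_moments_constant_data_gives_all_zero_components():
    fit = fit_moments(make_trait_table(np.full((3, 2, 2), 7.0)), "y")
    assert fit.sigma2_G == fit.sigma2_GT == fit.sigma2_T == 0.0
    assert fit.sigma2_E == 0.0


def test_moments_truncates_negative_solutions_to_zero():
    # large within-cell noise, tiny interaction: MS_GT < MS_E by construction
    rng = np.random.default_rng(3)
    found = False
    for s in range(30):
        cube = np.random.default_rng(s).normal(0, 1, (4, 3, 5))
        fit = fit_moments(make_trait_table(cube), "y")
        if fit.boundary:
            found = True
            assert fit.sigma2_G >= 0 and fit.sigma2_GT >= 0 and fit.sigma2_T >= 0
    assert found, "no boundary case encountered in 30 noise draws"


def test_moments_rejects_unbalanced_data():
    table = make_trait_table(np.zeros((3, 2, 2)))
    with pytest.raises(UnbalancedDataError, match="fit_reml"):
        fit_moments(table.iloc[:-1], "y")


# ---------------------------------------------------------------------------
# REML


def test_reml_matches_moments_on_balanced_interior_fit(small_sim):
    data = simulate_trial(small_sim)
    mom = fit_moments(data, "BDw")
    assert not mom.boundary
    reml = fit_reml(data, ModelSpec("BDw", tol=1e-12, max_iter=5000))
    for name in ("sigma2_T", "sigma2_G", "sigma2_GT", "sigma2_E"):
        assert getattr(reml, name) == pytest.approx(getattr(mom, name), rel=1e-6)
    assert reml.logREML == pytest.approx(mom.logREML, abs=1e-8)


def test_reml_loglik_matches_dense_covariance_oracle(small_sim):
    from phenotrial.mixedmodel import MixedModelWorkspace

    data = simulate_trial(small_sim)
    ws = MixedModelWorkspace(data, ModelSpec("BDw"))
    variances = dict(treatment=3.0, genotype=2.0, gxt=0.5)
    ll = ws.logREML(variances, 1.3)
    oracle = dense_mixed_model(data, "BDw", variances, 1.3)
    assert ll == pytest.approx(oracle["logREML"], abs=1e-8)


def test_reml_aic_identity_and_param_counts(small_sim):
    data = simulate_trial(small_sim)
    hom = fit_reml(data, ModelSpec("BDw", "homogeneous"))
    het = fit_reml(data, ModelSpec("BDw", "heterogeneous"))
    assert hom.n_params == 4 and het.n_params == 7
    for fit in (hom, het):
        assert fit.AIC == pytest.approx(-2 * fit.logREML + 2 * fit.n_params)
    assert het.residual_by_treatment().shape == (4,)


def test_reml_rejects_degenerate_designs():
    cube = np.zeros((1, 2, 2))
    with pytest.raises(ValueError, match="genotypes"):
        fit_reml(make_trait_table(cube), ModelSpec("y"))


# ---------------------------------------------------------------------------
# residual-model selection and LR test


def test_aic_selection_prefers_fewer_parameters_on_equal_likelihood():
    hom = _fit(logREML=-100.0, n_params=4, AIC=208.0)
    het = _fit(residual_model="heterogeneous", logREML=-100.0, n_params=7,
               AIC=214.0, sigma2_E=np.ones(2))
    assert select_residual_model(hom, het) is hom


def test_aic_selection_large_likelihood_gain_wins():
    hom = _fit(logREML=-110.0, n_params=4, AIC=228.0)
    het = _fit(residual_model="heterogeneous", logREML=-100.0, n_params=7,
               AIC=214.0, sigma2_E=np.ones(2))
    assert select_residual_model(hom, het) is het  # dAIC = -14


def test_aic_tie_goes_to_homogeneous():
    hom = _fit(AIC=100.0)
    het = _fit(residual_model="heterogeneous", AIC=100.0, n_params=7,
               sigma2_E=np.ones(2))
    assert select_residual_model(hom, het).residual_model == "homogeneous"


def test_aic_selection_rejects_different_traits():
    with pytest.raises(ValueError):
        select_residual_model(_fit("a"), _fit("b"))


def test_lr_test_boundary_mixture():
    full = _fit(logREML=-98.08, random_terms=("treatment", "genotype", "gxt"))
    red = _fit(logREML=-100.0, random_terms=("treatment", "genotype"))
    lr, p = lr_test_random(full, red)
    assert lr == pytest.approx(3.84)
    assert p == pytest.approx(0.025, abs=5e-4)  # half the chi2_1 tail

    equal = _fit(logREML=-100.0, random_terms=("treatment", "genotype"))
    lr0, p0 = lr_test_random(_fit(logREML=-100.0), equal)
    assert (lr0, p0) == (0.0, 1.0)

    worse = _fit(logREML=-99.0, random_terms=("treatment", "genotype"))
    lr_clip, p_clip = lr_test_random(_fit(logREML=-100.0), worse)
    assert (lr_clip, p_clip) == (0.0, 1.0)


def test_lr_test_rejects_non_nested_models():
    with pytest.raises(ValueError):
        lr_test_random(_fit(), _fit())  # same random terms, not nested


# ---------------------------------------------------------------------------
# heritability


@pytest.mark.parametrize(
    "sG,sGT,sE,expected",
    [(2.0, 1.0, 1.0, 0.5), (3.0, 0.0, 0.0, 1.0), (0.0, 1.0, 1.0, 0.0)],
)
def test_heritability_formula(sG, sGT, sE, expected):
    fit = _fit(sigma2_T=1.0, sigma2_G=sG, sigma2_GT=sGT, sigma2_E=sE)
    h2, shares = heritability_and_contributions(fit)
    assert h2 == pytest.approx(expected)
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)


def test_heritability_uses_mean_of_heterogeneous_residuals():
    fit = _fit(residual_model="heterogeneous", sigma2_G=2.0,
               sigma2_E=np.array([0.5, 1.5]))
    h2, _ = heritability_and_contributions(fit)
    assert h2 == pytest.approx(2.0 / 3.0)


def test_heritability_undefined_for_all_zero_fit():
    with pytest.raises(ValueError):
        heritability_and_contributions(_fit())


# ---------------------------------------------------------------------------
# BLUPs


def test_blups_equal_cell_means_without_residual_noise():
    rng = np.random.default_rng(8)
    g = rng.normal(0, 2, 4)
    gt = rng.normal(0, 1, (4, 3))
    cube = np.broadcast_to((5 + g[:, None] + gt)[:, :, None], (4, 3, 2)).copy()
    data = make_trait_table(cube)
    fit = fit_reml(data, ModelSpec("y", tol=1e-12, max_iter=5000))
    bm = blup_matrix(genotype_blups(fit, data))
    cell_means = cube.mean(axis=2)
    assert np.abs(bm.to_numpy() - cell_means).max() < 1e-6


def test_blups_collapse_to_treatment_mean_without_genetic_variance():
    cfg = SimConfig(n_genotypes=5, n_reps=4, sigma2_G=0.0, sigma2_GT=0.0,
                    sigma2_E=1.0, seed=9)
    data = simulate_trial(cfg)
    # full-shrinkage limit: a fit with zero genetic variance components
    fit = _fit(
        trait="BDw", treatments=cfg.treatments, sigma2_T=4.0, sigma2_E=1.0,
        n_obs=len(data),
    )
    bm = blup_matrix(genotype_blups(fit, data)).to_numpy()
    spread = bm.max(axis=0) - bm.min(axis=0)
    assert (spread < 1e-8).all()


def test_blups_match_dense_mixed_model_oracle(small_sim):
    data = simulate_trial(small_sim)
    fit = fit_reml(data, ModelSpec("BDw", tol=1e-12, max_iter=5000))
    bm = blup_matrix(genotype_blups(fit, data)).to_numpy()
    oracle = dense_mixed_model(
        data, "BDw",
        dict(treatment=fit.sigma2_T, genotype=fit.sigma2_G, gxt=fit.sigma2_GT),
        fit.sigma2_E,
    )
    assert np.abs(bm - oracle["predictions"]).max() < 1e-6


# ---------------------------------------------------------------------------
# diagnostics


def test_planted_outlier_is_the_only_flag():
    cfg = SimConfig(n_genotypes=6, n_reps=4, sigma2_G=1.0, sigma2_GT=0.2,
                    sigma2_E=0.5, seed=12)
    data = simulate_trial(cfg)
    data = data.copy()
    data.loc[37, "value"] += 10 * np.sqrt(0.5)
    fit = fit_reml(data, ModelSpec("BDw"))
    flagged = flag_outliers(data, fit, threshold=4.0)
    assert len(flagged) == 1
    target = data.loc[37]
    assert flagged.iloc[0]["genotype"] == target["genotype"]
    assert flagged.iloc[0]["replicate"] == target["replicate"]


def test_infinite_threshold_flags_nothing(small_sim):
    data = simulate_trial(small_sim)
    fit = fit_reml(data, ModelSpec("BDw"))
    assert flag_outliers(data, fit, threshold=np.inf).empty


def test_replicate_wald_detects_planted_replicate_effect():
    cfg = SimConfig(n_genotypes=10, n_reps=4, sigma2_G=1.0, sigma2_GT=0.2,
                    sigma2_E=0.3, replicate_effects=(0.0, 0.0, 0.0, 3.0),
                    seed=13)
    data = simulate_trial(cfg)
    fit = fit_reml(data, ModelSpec("BDw"))
    wald = replicate_wald_test(data, fit)
    assert len(wald) == 3
    last = wald.iloc[-1]
    assert last["p"] < 1e-6 and last["estimate"] == pytest.approx(3.0, abs=0.5)
    assert (wald.iloc[:2]["p"] > 0.01).all()
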