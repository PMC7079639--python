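"""Factor-analytic multi-site model: fitting, covariance, BLUPs."""

import numpy as np
import pandas as pd
import pytest

from metgain import FAModelFit, compute_blups, genetic_covariance, reml_fit_fa
from metgain.mixedmodel import reml_loglik, IIDTerm, FATerm

from conftest import make_fa_group


def _manual_fit(site_ids, genotype_names, lam, psi, **kw):
    lam = np.atleast_2d(np.asarray(lam, float))
    if lam.shape[0] == 1 and len(site_ids) > 1:
        lam = lam.T
    defaults = dict(
        group=("high_rainfall", 15), trait="gy_t_ha", site_ids=list(site_ids),
        genotype_names=list(genotype_names), k_factors=lam.shape[1],
        loadings=lam, specific_variances=np.asarray(psi, float),
        var_rep=0.0, var_block=0.0, var_genotype=0.0, var_residual=0.1,
        reml_loglik=0.0, n_iterations=0, converged=True,
    )
    defaults.update(kw)
    return FAModelFit(**defaults)


def test_single_site_input_is_rejected():
    df = pd.DataFrame(
        {
            "year": 15, "site_id": "S01", "rep": [1, 1, 2, 2], "block": 1,
            "entry": [1, 2, 1, 2], "genotype_name": ["A", "B", "A", "B"],
            "is_local_check": 0, "gy_t_ha": [4.0, 4.2, 4.1, 4.3],
        }
    )
    with pytest.raises(ValueError, match="single-site"):
        reml_fit_fa(df, "gy_t_ha")


def test_genetic_covariance_identities():
    fit = _manual_fit(["A", "B", "C"], ["G1", "G2"], np.zeros(3), [0.1, 0.2, 0.3])
    cov, cor = genetic_covariance(fit)
    np.testing.assert_allclose(cov.to_numpy(), np.diag([0.1, 0.2, 0.3]), atol=1e-12)
    # equal loadings, no specific variance, no main effect -> all correlations 1
    fit2 = _manual_fit(["A", "B"], ["G1", "G2"], [1.0, 1.0], [0.0, 0.0])
    _, cor2 = genetic_covariance(fit2)
    np.testing.assert_allclose(cor2.to_numpy(), 1.0, atol=1e-12)


def test_fitted_covariance_is_psd_with_bounded_correlations(small_program):
    _, plots, _, _ = small_program
    grp = plots[plots["year"] == plots["year"].min()]
    fit = reml_fit_fa(grp, "gy_t_ha")
    cov, cor = genetic_covariance(fit)
    w = np.linalg.eigvalsh(cov.to_numpy())
    assert w.min() >= -1e-10
    assert (cor.to_numpy() <= 1 + 1e-12).all() and (cor.to_numpy() >= -1 - 1e-12).all()
    # genotype main-effect BLUPs shrink around zero
    blup = compute_blups(fit, grp)
    scale = blup.genotype_table["blup_main"].abs().max()
    assert abs(blup.genotype_table["blup_main"].sum()) < max(0.05 * len(blup.genotype_table) * scale, 1e-8)


def test_blups_zero_when_variances_zero():
    rng = np.random.default_rng(2)
    plots, _ = make_fa_group(rng, n_sites=3, n_geno=8)
    fit = _manual_fit(
        sorted(plots["site_id"].unique()), sorted(plots["genotype_name"].unique()),
        np.zeros(3), np.zeros(3), var_residual=0.2,
    )
    blup = compute_blups(fit, plots)
    np.testing.assert_allclose(blup.site_table["blup"], 0.0, atol=1e-10)
    np.testing.assert_allclose(
        blup.genotype_table["across_site_mean"], blup.grand_mean, atol=1e-10
    )


def test_perfect_correlation_borrows_prediction_across_sites():
    """With corr(A,B)=1 and equal variances, site-B prediction equals site-A."""
    rng = np.random.default_rng(4)
    rows = []
    for g in range(6):
        for r in (1, 2):
            rows.append({"year": 15, "site_id": "A", "rep": r, "block": 1,
                         "entry": g + 1, "genotype_name": f"G{g}",
                         "is_local_check": 0,
                         "gy_t_ha": 4 + 0.5 * g + rng.normal(0, 0.05)})
    # site B observes only half the genotypes
    for g in range(3):
        for r in (1, 2):
            rows.append({"year": 15, "site_id": "B", "rep": r, "block": 1,
                         "entry": g + 1, "genotype_name": f"G{g}",
                         "is_local_check": 0,
                         "gy_t_ha": 5 + 0.5 * g + rng.normal(0, 0.05)})
    plots = pd.DataFrame(rows)
    fit = _manual_fit(["A", "B"], [f"G{g}" for g in range(6)],
                      [0.7, 0.7], [0.0, 0.0], var_residual=0.05)
    blup = compute_blups(fit, plots)
    st = blup.site_table.set_index(["genotype_name", "site_id"])["blup"]
    for g in range(3, 6):   # unobserved at B
        assert st[(f"G{g}", "B")] == pytest.approx(st[(f"G{g}", "A")], abs=1e-6)
        assert not blup.site_table.set_index(["genotype_name", "site_id"])["observed"][(f"G{g}", "B")]


def test_compound_symmetry_limit_of_fa1():
    """Equal loadings with zero specific variance imply correlation ~1 site pairs."""
    rng = np.random.default_rng(10)
    plots, _ = make_fa_group(
        rng, n_sites=4, n_geno=40, lam=np.full(4, 0.6), psi=np.zeros(4),
        sig2_g=0.15, sig2_e=0.1,
    )
    fit = reml_fit_fa(plots, "gy_t_ha")
    _, cor = genetic_covariance(fit)
    off = cor.to_numpy()[np.triu_indices(4, 1)]
    assert np.median(off) >= 0.98


def test_reml_loglik_at_estimate_not_below_truth():
    rng = np.random.default_rng(14)
    lam_t = np.array([0.4, 0.6, 0.8, 0.5])
    psi_t = np.array([0.05, 0.08, 0.04, 0.1])
    plots, truth = make_fa_group(rng, n_sites=4, n_geno=30, lam=lam_t, psi=psi_t)
    fit = reml_fit_fa(plots, "gy_t_ha")
    df = plots.sort_values(["site_id", "rep", "block", "genotype_name"]).reset_index(drop=True)
    site = pd.Categorical(df["site_id"]).codes
    geno = pd.Categorical(df["genotype_name"]).codes
    rep = pd.Categorical(list(zip(df["site_id"], df["rep"]))).codes
    blk = pd.Categorical(list(zip(df["site_id"], df["rep"], df["block"]))).codes
    n = len(df)
    X = np.column_stack([np.ones(n)] + [(site == s).astype(float) for s in range(1, 4)])
    terms = [IIDTerm("rep", rep, rep.max() + 1), IIDTerm("block", blk, blk.max() + 1),
             IIDTerm("genotype", geno, geno.max() + 1)]
    fa = FATerm(site, geno, 4, geno.max() + 1, 1)
    l_truth = reml_loglik(
        df["gy_t_ha"].to_numpy(), X, terms, fa,
        {"rep": 0.03, "block": 0.03, "genotype": truth["sig2_g"]},
        truth["sig2_e"], lam_t, np.maximum(psi_t, 1e-8),
    )
    assert fit.reml_loglik >= l_truth - 1e-6


def test_model_implied_observation_variance_matches_empirical():
    """Var(y) at site j should be sig2_g + Sigma_s[j,j] + sig2_r + sig2_b + sig2_e."""
    rng = np.random.default_rng(18)
    lam_t = np.array([0.4, 0.8])
    psi_t = np.array([0.05, 0.1])
    plots, truth = make_fa_group(
        rng, n_sites=2, n_geno=4000, n_blocks=8, lam=lam_t, psi=psi_t,
    )
    for j, sid in enumerate(["S01", "S02"]):
        y = plots.loc[plots["site_id"] == sid, "gy_t_ha"].to_numpy()
        implied = 0.2 + lam_t[j] ** 2 + psi_t[j] + 0.03 + 0.03 + 0.16
        assert np.var(y, ddof=1) == pytest.approx(implied, rel=0.1)


def test_poorly_connected_site_is_flagged():
    rng = np.random.default_rng(6)
    plots, _ = make_fa_group(rng, n_sites=3, n_geno=10)
    # site S03 keeps a single genotype shared with the others
    mask = (plots["site_id"] == "S03") & (plots["genotype_name"] != "G00")
    with pytest.warns(UserWarning, match="shared"):
        reml_fit_fa(plots[~mask], "gy_t_ha")
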