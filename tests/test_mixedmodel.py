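"""Core REML engine and mixed-model-equation solver."""

import numpy as np
import pandas as pd
import pytest

from metgain.mixedmodel import (
    FATerm,
    IIDTerm,
    _REMLProblem,
    fa_covariance,
    reml_fit,
    reml_loglik,
    solve_mme,
)

from oracles import gls_oracle


def _layout(rng, S=3, G=8, R=2):
    site = np.repeat(np.arange(S), G * R)
    rep = np.tile(np.repeat(np.arange(R), G), S)
    geno = np.tile(np.arange(G), S * R)
    blk = np.concatenate([rng.permutation(G) % 2 for _ in range(S * R)])
    n = len(site)
    X = np.column_stack([np.ones(n)] + [(site == s).astype(float) for s in range(1, S)])
    terms = [
        IIDTerm("rep", site * R + rep, S * R),
        IIDTerm("block", (site * R + rep) * 2 + blk, S * R * 2),
        IIDTerm("geno", geno, G),
    ]
    fa = FATerm(site, geno, S, G, 1)
    return X, terms, fa, site, geno


def test_analytic_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    X, terms, fa, *_ = _layout(rng)
    y = rng.normal(4, 1, X.shape[0])
    prob = _REMLProblem(y, X, terms, fa)
    theta = rng.normal(-1.0, 0.4, prob.n_params())
    _, grad = prob.neg_loglik_grad(theta)
    eps = 1e-6
    for i in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        fd = (prob.neg_loglik_grad(tp)[0] - prob.neg_loglik_grad(tm)[0]) / (2 * eps)
        assert grad[i] == pytest.approx(fd, abs=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_mme_matches_dense_gls_oracle(seed):
    """BLUPs and fixed effects equal direct marginal-covariance GLS."""
    rng = np.random.default_rng(seed)
    X, terms, fa, site, geno = _layout(rng)
    n = X.shape[0]
    y = rng.normal(4, 1, n)
    variances = {"rep": 0.05, "block": 0.04, "geno": 0.3}
    lam = rng.uniform(0.2, 0.7, fa.n_sites)[:, None]
    psi = rng.uniform(0.02, 0.1, fa.n_sites)
    sig2_e = 0.25
    sol = solve_mme(y, X, terms, variances, sig2_e, fa, lam, psi)

    Sigma = fa_covariance(lam, psi)
    Zs = [t.design(n) for t in terms] + [fa.design(n)]
    Gs = [variances[t.name] * np.eye(t.n_levels) for t in terms] + [
        np.kron(Sigma, np.eye(fa.n_geno))
    ]
    beta_o, us_o = gls_oracle(y, X, Zs, Gs, sig2_e)
    np.testing.assert_allclose(sol.fixed_effects, beta_o, atol=1e-8)
    for t, u_o in zip(terms, us_o[:-1]):
        np.testing.assert_allclose(sol.random_effects[t.name], u_o, atol=1e-8)
    np.testing.assert_allclose(sol.random_effects["ge"], us_o[-1], atol=1e-8)


def test_mme_shrinkage_limits():
    """Variance -> 0 shrinks BLUPs to zero; residual -> 0 stops shrinking."""
    rng = np.random.default_rng(3)
    X, terms, fa, site, geno = _layout(rng)
    n = X.shape[0]
    y = rng.normal(4, 1, n)
    lam = np.full((fa.n_sites, 1), 0.5)
    psi = np.full(fa.n_sites, 0.05)
    sol0 = solve_mme(
        y, X, terms, {"rep": 0.0, "block": 0.0, "geno": 0.0}, 0.3, fa,
        np.zeros((fa.n_sites, 1)), np.zeros(fa.n_sites),
    )
    assert np.allclose(sol0.random_effects["geno"], 0.0)
    assert np.allclose(sol0.random_effects["ge"], 0.0)
    # near-zero residual: genotype BLUP + ge approaches per-cell deviations
    sol1 = solve_mme(
        y, X, terms, {"rep": 0.0, "block": 0.0, "geno": 10.0}, 1e-8, fa,
        lam, psi,
    )
    cells = pd.DataFrame({"site": site, "geno": geno, "y": y})
    cell_means = cells.groupby(["site", "geno"])["y"].mean()
    mu = sol1.fixed_effects[0]
    site_eff = np.concatenate([[0.0], sol1.fixed_effects[1:]])
    ge = sol1.random_effects["ge"].reshape(fa.n_sites, fa.n_geno)
    g = sol1.random_effects["geno"]
    for (s, gg), m in cell_means.items():
        pred = mu + site_eff[s] + g[gg] + ge[s, gg]
        assert pred == pytest.approx(m, abs=1e-3)


def test_reml_matches_statsmodels_random_intercept():
    """Cross-check against an independent REML implementation (MixedLM)."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(11)
    n_groups, per = 25, 6
    groups = np.repeat(np.arange(n_groups), per)
    x = rng.normal(size=n_groups * per)
    u = rng.normal(0, 1.2, n_groups)
    y = 2.0 + 0.5 * x + u[groups] + rng.normal(0, 0.8, n_groups * per)
    X = np.column_stack([np.ones_like(x), x])
    res = reml_fit(y, X, [IIDTerm("grp", groups, n_groups)])
    m = sm.MixedLM(y, X, groups=groups).fit(reml=True)
    assert res.variances["grp"] == pytest.approx(float(np.asarray(m.cov_re)[0, 0]), rel=1e-4)
    assert res.residual_variance == pytest.approx(float(m.scale), rel=1e-4)


def test_scale_equivariance():
    """Multiplying the response by c scales variances by c^2 and loadings by c."""
    rng = np.random.default_rng(5)
    X, terms, fa, *_ = _layout(rng)
    y = 4 + rng.normal(0, 0.8, X.shape[0])
    r1 = reml_fit(y, X, terms, fa)
    r2 = reml_fit(1000.0 * y, X, terms, fa)
    for name in r1.variances:
        assert r2.variances[name] == pytest.approx(1e6 * r1.variances[name], rel=1e-3, abs=1e-4)
    assert r2.residual_variance == pytest.approx(1e6 * r1.residual_variance, rel=1e-3)
    np.testing.assert_allclose(r2.loadings, 1000.0 * r1.loadings, rtol=1e-2, atol=1e-2)


def test_loading_sign_flip_leaves_likelihood_unchanged_and_canonical():
    rng = np.random.default_rng(8)
    X, terms, fa, *_ = _layout(rng)
    y = rng.normal(4, 1, X.shape[0])
    variances = {"rep": 0.05, "block": 0.04, "geno": 0.3}
    lam = np.array([0.5, -0.3, 0.4])
    psi = np.array([0.05, 0.08, 0.03])
    l_plus = reml_loglik(y, X, terms, fa, variances, 0.3, lam, psi)
    l_minus = reml_loglik(y, X, terms, fa, variances, 0.3, -lam, psi)
    assert l_plus == pytest.approx(l_minus, abs=1e-9)
    fit = reml_fit(y, X, terms, fa)
    lead = fit.loadings[np.flatnonzero(np.abs(fit.loadings[:, 0]) > 1e-9)[0], 0]
    assert lead > 0


def test_higher_fa_order_never_lowers_reml_loglik(small_program):
    _, plots, _, _ = small_program
    from metgain import reml_fit_fa

    grp = plots[plots["year"] == plots["year"].min()]
    f1 = reml_fit_fa(grp, "gy_t_ha", k_factors=1)
    f2 = reml_fit_fa(grp, "gy_t_ha", k_factors=2)
    assert f2.reml_loglik >= f1.reml_loglik - 1e-6
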