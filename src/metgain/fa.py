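"""Multi-site mixed model with factor-analytic genotype-by-site covariance.

The model for a group of sites (one environment group in one nursery year) is

    y = 1 mu + X_s s + Z_r r + Z_b b + Z_g g + Z_ge ge + e

with fixed site effects and independent random replicates-within-site,
blocks-within-replicate, genotype main effects (sig2_g I) and a
genotype-by-site term whose covariance is the Kronecker product of a
factor-analytic site matrix Sigma_s = Lam Lam' + diag(psi) with an identity
over genotypes.  REML estimates the variance parameters; Henderson's
mixed-model equations then yield BLUPs of every genotype's total genetic
value in every site, including sites where it was not observed (information
is borrowed through Sigma_s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedmodel import IIDTerm, FATerm, REMLResult, fa_covariance, reml_fit, solve_mme

__all__ = ["FAModelFit", "BlupTable", "reml_fit_fa", "compute_blups", "genetic_covariance"]


@dataclass
class FAModelFit:
    """REML fit of the multi-site factor-analytic model for one group."""

    group: tuple                      # (environment label, nursery year) or similar
    trait: str
    site_ids: list                    # ordering defines the Sigma_s dimension
    genotype_names: list
    k_factors: int
    loadings: np.ndarray              # (n_sites, k)
    specific_variances: np.ndarray    # (n_sites,)
    var_rep: float
    var_block: float
    var_genotype: float
    var_residual: float
    reml_loglik: float
    n_iterations: int
    converged: bool
    include_main_effect: bool = True
    flags: list = field(default_factory=list)
    n_obs: int = 0
    n_params: int = 0

    def site_covariance(self) -> np.ndarray:
        return fa_covariance(self.loadings, self.specific_variances)

    @property
    def aic(self) -> float:
        return -2.0 * self.reml_loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.reml_loglik + self.n_params * np.log(max(self.n_obs, 1))


@dataclass
class BlupTable:
    """Predicted genetic values for one fitted group."""

    group: tuple
    trait: str
    site_table: pd.DataFrame       # genotype_name, site_id, blup (g + ge), se, observed
    genotype_table: pd.DataFrame   # genotype_name, blup_main, across_site_mean, is_local_check
    lc_mean: float                 # observed mean yield of the local checks (trait units)
    lc_predicted_mean: float       # shrunk (BLUP-based) local-check mean
    grand_mean: float              # mu + average fixed site effect
    excluded_genotypes: list = field(default_factory=list)


def _design(plots: pd.DataFrame, trait: str, k_factors: int):
    """Shared design construction for REML and the MME solver."""
    df = plots.dropna(subset=[trait]).reset_index(drop=True)
    site_cat = pd.Categorical(df["site_id"])
    geno_cat = pd.Categorical(df["genotype_name"])
    site_codes = site_cat.codes.astype(np.intp)
    geno_codes = geno_cat.codes.astype(np.intp)
    S, G = len(site_cat.categories), len(geno_cat.categories)
    n = len(df)
    X = np.ones((n, S))
    X[:, 1:] = 0.0
    for j in range(1, S):
        X[:, j] = (site_codes == j).astype(float)
    rep_codes = pd.Categorical(list(zip(df["site_id"], df["rep"]))).codes.astype(np.intp)
    blk_codes = pd.Categorical(
        list(zip(df["site_id"], df["rep"], df["block"]))
    ).codes.astype(np.intp)
    terms = [
        IIDTerm("rep", rep_codes, int(rep_codes.max()) + 1),
        IIDTerm("block", blk_codes, int(blk_codes.max()) + 1),
    ]
    fa = FATerm(site_codes, geno_codes, S, G, k_factors)
    y = df[trait].to_numpy(float)
    return df, y, X, terms, fa, list(site_cat.categories), list(geno_cat.categories)


def reml_fit_fa(
    plots: pd.DataFrame,
    trait: str = "gy_t_ha",
    k_factors: int = 1,
    group: tuple = ("all", 0),
    include_main_effect: bool = True,
    max_iter: int = 300,
    gtol: float = 2e-5,
) -> FAModelFit:
    """REML fit of the factor-analytic multi-site model on one group of sites.

    ``include_main_effect`` keeps the explicit genotype main variance sig2_g
    alongside the factor-analytic deviations (the default); setting it False
    collapses the main effect into Sigma_s, the pure factor-analytic
    parameterisation (the two forms are weakly identified against each
    other).
    """
    if plots.dropna(subset=[trait])["site_id"].nunique() < 2:
        raise ValueError(
            "multi-site model needs >= 2 sites; use single-site analysis "
            "(fit_site_model) for one site"
        )
    df, y, X, terms, fa, site_ids, geno_names = _design(plots, trait, k_factors)
    flags: list[str] = []
    # connectivity: a site sharing < 2 genotypes with the rest cannot anchor psi
    geno_sets = df.groupby("site_id")["genotype_name"].agg(set)
    for sid in site_ids:
        others = set().union(*(geno_sets[s] for s in site_ids if s != sid))
        if len(geno_sets[sid] & others) < 2:
            flags.append(f"site {sid}: <2 genotypes shared with other sites")
            warnings.warn(flags[-1], stacklevel=2)
    if include_main_effect:
        terms = terms + [IIDTerm("genotype", fa.geno_codes, fa.n_geno)]
    res: REMLResult = reml_fit(y, X, terms, fa, max_iter=max_iter, gtol=gtol)
    if not res.converged:
        flags.append("non_convergence:best_iterate_returned")
    psi = np.asarray(res.specific_variances, float)
    if np.any(psi <= 2e-8):
        flags.append("specific_variance_at_boundary")
    n_params = len(terms) + 1 + int(np.sum(fa.loading_mask())) + fa.n_sites
    return FAModelFit(
        group=group,
        trait=trait,
        site_ids=site_ids,
        genotype_names=geno_names,
        k_factors=k_factors,
        loadings=np.asarray(res.loadings, float),
        specific_variances=psi,
        var_rep=res.variances["rep"],
        var_block=res.variances["block"],
        var_genotype=res.variances.get("genotype", 0.0),
        var_residual=res.residual_variance,
        reml_loglik=res.loglik,
        n_iterations=res.n_iterations,
        converged=res.converged,
        include_main_effect=include_main_effect,
        flags=flags,
        n_obs=len(y),
        n_params=n_params,
    )


def compute_blups(fit: FAModelFit, plots: pd.DataFrame) -> BlupTable:
    """Solve the mixed-model equations at the fitted variances and assemble BLUPs.

    Every (genotype, site) combination of the group receives a prediction of
    its total genetic value g + ge; the across-site predicted mean adds the
    overall mean and the average fixed site effect.  The local-check mean is
    the average of the predicted values of all local-check entries in the
    group.
    """
    df, y, X, terms, fa, site_ids, geno_names = _design(plots, fit.trait, fit.k_factors)
    if site_ids != fit.site_ids or geno_names != fit.genotype_names:
        raise ValueError("plots do not match the fitted group")
    variances = {"rep": fit.var_rep, "block": fit.var_block}
    if fit.include_main_effect:
        terms = terms + [IIDTerm("genotype", fa.geno_codes, fa.n_geno)]
        variances["genotype"] = fit.var_genotype
    sol = solve_mme(
        y, X, terms, variances, fit.var_residual,
        fa_term=fa, loadings=fit.loadings, specific_variances=fit.specific_variances,
    )
    if sol.singular:
        warnings.warn("singular mixed-model equations: minimum-norm solution used",
                      stacklevel=2)
    S, G = fa.n_sites, fa.n_geno
    g_main = sol.random_effects.get("genotype", np.zeros(G))
    ge = sol.random_effects["ge"].reshape(S, G)
    pev_ge = sol.prediction_error_var["ge"].reshape(S, G)
    mu = sol.fixed_effects[0]
    site_eff = np.concatenate([[0.0], sol.fixed_effects[1:S]])
    grand_mean = float(mu + site_eff.mean())

    observed = np.zeros((S, G), dtype=bool)
    observed[fa.site_codes, fa.geno_codes] = True
    site_table = pd.DataFrame(
        {
            "genotype_name": np.tile(geno_names, S),
            "site_id": np.repeat(site_ids, G),
            "blup": (g_main[None, :] + ge).ravel(),
            "se": np.sqrt(pev_ge).ravel(),
            "observed": observed.ravel(),
        }
    )
    lc_flag = (
        df.groupby("genotype_name")["is_local_check"].max().reindex(geno_names)
        .fillna(0).astype(bool)
    )
    across = g_main + ge.mean(axis=0)
    genotype_table = pd.DataFrame(
        {
            "genotype_name": geno_names,
            "blup_main": g_main,
            "across_site_blup": across,
            "across_site_mean": grand_mean + across,
            "is_local_check": lc_flag.to_numpy(),
        }
    )
    # two check benchmarks: the observed mean yield of the checks across all
    # their plots in the group (unshrunk, robust to the strong shrinkage of
    # one-site entries) and the shrunk BLUP-based predicted mean
    lc_plots = df.loc[df["is_local_check"].astype(bool), fit.trait]
    lc_mean = float(lc_plots.mean()) if len(lc_plots) else float("nan")
    lc_vals = genotype_table.loc[genotype_table["is_local_check"], "across_site_mean"]
    lc_pred = float(lc_vals.mean()) if len(lc_vals) else float("nan")
    excluded = sorted(set(plots["genotype_name"]) - set(geno_names))
    if excluded:
        warnings.warn(
            f"{len(excluded)} genotype(s) without data for {fit.trait} excluded",
            stacklevel=2,
        )
    return BlupTable(
        group=fit.group,
        trait=fit.trait,
        site_table=site_table,
        genotype_table=genotype_table,
        lc_mean=lc_mean,
        lc_predicted_mean=lc_pred,
        grand_mean=grand_mean,
        excluded_genotypes=excluded,
    )


def genetic_covariance(fit: FAModelFit):
    """Site-by-site genetic covariance and correlation implied by the fit.

    The covariance is Sigma_s = Lam Lam' + diag(psi); correlations include
    the genotype main variance, i.e. the total genetic covariance between
    sites i and j is sig2_g + Sigma_s[i, j].
    """
    Sigma = fit.site_covariance()
    total = Sigma + fit.var_genotype
    d = np.sqrt(np.diag(total))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = total / np.outer(d, d)
    corr = np.where(np.outer(d, d) > 0, corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    cov = pd.DataFrame(Sigma, index=fit.site_ids, columns=fit.site_ids)
    cor = pd.DataFrame(corr, index=fit.site_ids, columns=fit.site_ids)
    return cov, cor
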