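"""Per-site alpha-lattice analysis: variance components, heritability, filtering.

Each site is analysed with a linear mixed model with fixed replicate and
genotype effects and random incomplete blocks nested in replicates; a
companion refit with genotypes random supplies the genotype variance needed
for heritability.  Sites whose entry-mean heritability falls below a
threshold (default 0.05) are screened out before any multi-site analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedmodel import IIDTerm, reml_fit

__all__ = ["SiteFit", "fit_site_model", "estimate_heritability", "filter_sites"]


@dataclass
class SiteFit:
    """Variance components and heritability of one trial site."""

    site_id: str
    trait: str
    grand_mean: float
    rep_effects: dict
    block_variance: float
    genotype_variance: float
    residual_variance: float
    heritability: float
    n_reps: int
    n_genotypes: int
    genotype_adjusted_means: pd.Series
    converged: bool
    flags: list = field(default_factory=list)
    loglik: float = float("nan")
    grad_norm: float = float("nan")


def _codes(values) -> tuple[np.ndarray, list]:
    cats = pd.Categorical(values)
    return cats.codes.astype(np.intp), list(cats.categories)


def fit_site_model(plots: pd.DataFrame, trait: str = "gy_t_ha") -> SiteFit:
    """Fit the per-site incomplete-block model for one trait.

    Returns REML estimates of the block and residual variances with fixed
    replicate and genotype effects, adjusted genotype means from that fit,
    and a genotype variance from a companion random-genotype refit used for
    heritability.  Degenerate layouts (no block structure, genotypes seen in
    a single replicate, constant data) are handled and flagged rather than
    fatal.
    """
    df = plots.dropna(subset=[trait]).copy()
    sites = df["site_id"].unique()
    if len(sites) != 1:
        raise ValueError(f"fit_site_model expects one site, got {list(sites)}")
    site_id = str(sites[0])
    n_reps = df["rep"].nunique()
    if n_reps < 2:
        raise ValueError(f"site {site_id}: need >= 2 replicates, found {n_reps}")
    if df["genotype_name"].nunique() < 2:
        raise ValueError(f"site {site_id}: need >= 2 genotypes with data")

    flags: list[str] = []
    y = df[trait].to_numpy(float)
    geno_codes, geno_levels = _codes(df["genotype_name"])
    rep_codes, rep_levels = _codes(df["rep"])
    n, G = len(df), len(geno_levels)

    # genotypes observed in a single replicate make the fixed design singular
    reps_per_geno = df.groupby("genotype_name")["rep"].nunique()
    if (reps_per_geno < 2).any():
        flags.append("singular_design:genotypes_in_one_rep")

    # block structure: blocks nested in replicates; absent or degenerate -> 0
    has_blocks = "block" in df.columns and df.groupby("rep")["block"].nunique().max() > 1
    if not has_blocks:
        flags.append("no_block_structure:block_variance_fixed_0")
        block_term = None
    else:
        blk_codes, _ = _codes(list(zip(df["rep"], df["block"])))
        block_term = IIDTerm("block", blk_codes, int(blk_codes.max()) + 1)

    # constant data: every variance is zero by definition
    if float(np.var(y)) < 1e-14:
        flags.append("constant_data")
        means = pd.Series(y[0] if n else np.nan, index=pd.Index(geno_levels))
        return SiteFit(
            site_id=site_id, trait=trait, grand_mean=float(np.mean(y)),
            rep_effects={r: 0.0 for r in rep_levels}, block_variance=0.0,
            genotype_variance=0.0, residual_variance=0.0, heritability=0.0,
            n_reps=n_reps, n_genotypes=G, genotype_adjusted_means=means,
            converged=True, flags=flags,
        )

    # --- fit 1: fixed mu + rep + genotype; random blocks ------------------
    X_cols = [np.ones(n)]
    for j in range(1, len(rep_levels)):
        X_cols.append((rep_codes == j).astype(float))
    for g in range(1, G):
        X_cols.append((geno_codes == g).astype(float))
    X = np.column_stack(X_cols)
    terms = [block_term] if block_term is not None else []
    fit_fixed = reml_fit(y, X, terms, tol=1e-13, gtol=1e-9)

    # adjusted genotype means: intercept + genotype contrast + average rep effect
    beta = fit_fixed.fixed_effects
    if beta is None or len(beta) != X.shape[1]:
        # rank-deficient fixed design: fall back to least squares on full X
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        flags.append("rank_deficient_fixed_design")
    n_rep_eff = len(rep_levels) - 1
    rep_eff = np.concatenate([[0.0], beta[1 : 1 + n_rep_eff]])
    geno_eff = np.concatenate([[0.0], beta[1 + n_rep_eff : 1 + n_rep_eff + G - 1]])
    adj = beta[0] + rep_eff.mean() + geno_eff
    means = pd.Series(adj, index=pd.Index(geno_levels))
    rep_effects = {r: float(e) for r, e in zip(rep_levels, rep_eff)}

    # --- fit 2: genotypes random, for the heritability variance ----------
    X2 = np.column_stack(X_cols[: 1 + n_rep_eff])
    terms2 = [IIDTerm("genotype", geno_codes, G)]
    if block_term is not None:
        terms2.append(IIDTerm("block", block_term.codes, block_term.n_levels))
    fit_rand = reml_fit(y, X2, terms2, tol=1e-13, gtol=1e-9)

    sig2_g = fit_rand.variances["genotype"]
    sig2_e = fit_rand.residual_variance
    converged = bool(fit_fixed.converged and fit_rand.converged)
    if not converged:
        flags.append("non_convergence")
    result = SiteFit(
        site_id=site_id, trait=trait, grand_mean=float(beta[0] + rep_eff.mean()),
        rep_effects=rep_effects,
        block_variance=float(fit_fixed.variances.get("block", 0.0)),
        genotype_variance=float(sig2_g),
        residual_variance=float(sig2_e),
        heritability=0.0,
        n_reps=n_reps, n_genotypes=G,
        genotype_adjusted_means=means, converged=converged, flags=flags,
        loglik=fit_rand.loglik, grad_norm=fit_rand.grad_norm,
    )
    result.heritability = estimate_heritability(result)
    return result


def estimate_heritability(fit: SiteFit, basis: str = "entry_mean") -> float:
    """Heritability from a site's variance components, clamped to [0, 1].

    ``entry_mean`` (default): sig2_g / (sig2_g + sig2_e / r), the repeatability
    of genotype means over r replicates.  ``plot``: sig2_g over the total
    plot-level variance including block variance.
    """
    g, e, b, r = (
        fit.genotype_variance,
        fit.residual_variance,
        fit.block_variance,
        fit.n_reps,
    )
    if basis == "entry_mean":
        denom = g + e / max(r, 1)
    elif basis == "plot":
        denom = g + b + e
    else:
        raise ValueError(f"unknown heritability basis {basis!r}")
    if denom <= 0:
        warnings.warn(
            f"site {fit.site_id}: all variance components zero; H2 set to 0",
            stacklevel=2,
        )
        return 0.0
    return float(min(max(g / denom, 0.0), 1.0))


def filter_sites(fits, threshold: float = 0.05):
    """Apply the low-heritability screen: sites with H2 < threshold are dropped.

    Returns ``(retained_site_ids, report)`` where the report lists every site
    with its heritability, decision and reason.  The boundary is retained
    (exclusion uses the strict inequality H2 < threshold).
    """
    fits = list(fits)
    if not fits:
        warnings.warn("filter_sites received no site fits", stacklevel=2)
        return [], pd.DataFrame(
            columns=["site_id", "heritability", "retained", "reason"]
        )
    rows = []
    retained = []
    for fit in fits:
        keep = fit.heritability >= threshold
        reason = "" if keep else f"H2={fit.heritability:.4f} < {threshold}"
        rows.append((fit.site_id, fit.heritability, keep, reason))
        if keep:
            retained.append(fit.site_id)
    report = pd.DataFrame(rows, columns=["site_id", "heritability", "retained", "reason"])
    return retained, report
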