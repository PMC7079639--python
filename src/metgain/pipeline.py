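"""End-to-end orchestration: site fits -> H2 filter -> classification ->
per-group factor-analytic fits -> gain regressions -> trait analysis.

Each stage persists its tables under the configured output directory and is
recorded in a manifest with input/output counts, warnings and file
checksums, so a run is reproducible from the manifest plus the inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__ as _version
from .classify import classify_sites, label_clusters
from .config import RunConfig
from .fa import compute_blups, genetic_covariance, reml_fit_fa
from .gains import (
    estimate_gylc_gain,
    estimate_gyp_gain,
    select_top_lines,
    yearly_yield_distribution,
)
from .io import RunManifest, read_climate_table, read_plot_table, write_table
from .site import filter_sites, fit_site_model
from .traits import biplot_decomposition, derive_traits, sequential_r2, trait_trend

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger("metgain")

TRAIT_LABELS = {
    "gw_mg": "GW", "gn": "GN", "dm": "DM", "dhm": "DHM", "dh": "DH", "ph_cm": "PH",
}


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run (everything is also on disk)."""

    manifest: RunManifest
    site_fits: list = field(default_factory=list)
    retained_sites: list = field(default_factory=list)
    env_assignment: object = None
    group_fits: dict = field(default_factory=dict)      # (env, year) -> FAModelFit
    group_blups: dict = field(default_factory=dict)     # (env, year) -> BlupTable
    gains: list = field(default_factory=list)
    hyl: dict = field(default_factory=dict)             # (env, year) -> HYLSelection
    trait_trends: pd.DataFrame | None = None
    trait_contributions: object = None
    biplot: object = None


def _log(config: RunConfig, msg: str) -> None:
    if config.verbosity >= 1:
        logger.info(msg)


def run_pipeline(config: RunConfig, plots=None, climate=None) -> PipelineResult:
    """Execute the full analysis chain.

    ``plots`` and ``climate`` may be passed as DataFrames; otherwise they are
    read from the paths in the config.  Stage failures are recorded in the
    manifest, downstream stages are skipped, and the exception is re-raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from dataclasses import asdict

    manifest = RunManifest(asdict(config), _version, config.seed)
    result = PipelineResult(manifest=manifest)
    try:
        _run_stages(config, plots, climate, out, manifest, result)
        manifest.finish(completed=True)
    except Exception as exc:
        manifest.warn(f"pipeline aborted: {exc}")
        manifest.finish(completed=False)
        manifest.write(out / "manifest.yaml")
        raise
    manifest.write(out / "manifest.yaml")
    return result


def _run_stages(config, plots, climate, out, manifest, result) -> None:
    # --- stage: input ------------------------------------------------------
    if plots is None:
        plots, report = read_plot_table(config.plot_table)
        for w in report["warnings"]:
            manifest.warn(w)
    if climate is None:
        climate = read_climate_table(config.climate_table)
    manifest.record_stage("read", len(plots), len(plots))
    _log(config, f"read {len(plots)} plots, {climate['site_id'].nunique()} sites")

    # --- stage: per-site fits and heritability screen ----------------------
    fits = []
    for site_id, grp in plots.groupby("site_id"):
        try:
            fits.append(fit_site_model(grp, config.yield_trait))
        except ValueError as exc:
            manifest.warn(f"site {site_id} skipped: {exc}")
    result.site_fits = fits
    retained, filter_report = filter_sites(fits, config.h2_threshold)
    result.retained_sites = retained
    site_rows = [
        {
            "site_id": f.site_id, "trait": f.trait, "grand_mean": f.grand_mean,
            "block_variance": f.block_variance,
            "genotype_variance": f.genotype_variance,
            "residual_variance": f.residual_variance,
            "heritability": f.heritability, "n_reps": f.n_reps,
            "converged": f.converged, "flags": ";".join(f.flags),
        }
        for f in fits
    ]
    manifest.record_output("site_fits", write_table(pd.DataFrame(site_rows), out / "site_fits.csv"))
    manifest.record_output("site_filter", write_table(filter_report, out / "site_filter.csv"))
    manifest.record_stage("site_filter", len(fits), len(retained),
                          threshold=config.h2_threshold)
    _log(config, f"retained {len(retained)}/{len(fits)} sites at H2 >= {config.h2_threshold}")
    if not retained:
        raise ValueError(
            "no sites retained after the heritability screen (empty retention); "
            "lower h2_threshold or check the input data"
        )

    # --- stage: environment classification ---------------------------------
    clim_used = climate[climate["site_id"].isin(retained)]
    assignment = classify_sites(
        clim_used, k=config.kmeans_k, restarts=config.kmeans_restarts, seed=config.seed
    )
    assignment = label_clusters(assignment, clim_used)
    result.env_assignment = assignment
    labels = assignment.assignments.set_index("site_id")["label"]
    manifest.record_output(
        "env_assignments", write_table(assignment.assignments, out / "env_assignments.csv")
    )
    manifest.record_stage("classify", len(retained), len(labels))
    _log(config, f"classified {len(labels)} sites into "
                 f"{assignment.assignments['label'].value_counts().to_dict()}")

    # --- stage: per-group factor-analytic fits ------------------------------
    # derived traits (DHM, GN) are computed at plot level and modelled like
    # any measured trait, so their BLUPs come from their own mixed-model fits
    plots_kept = derive_traits(plots[plots["site_id"].isin(retained)].copy())
    plots_kept["env"] = plots_kept["site_id"].map(labels)
    var_rows, cov_rows, blup_rows, blup_site_rows = [], [], [], []
    for (env, year), grp in plots_kept.groupby(["env", "year"]):
        if grp["site_id"].nunique() < config.min_sites_per_group:
            manifest.warn(f"group ({env}, {year}): fewer than "
                          f"{config.min_sites_per_group} sites, skipped")
            continue
        fit = reml_fit_fa(grp, config.yield_trait, config.fa_order, group=(env, year))
        blup = compute_blups(fit, grp)
        result.group_fits[(env, year)] = fit
        result.group_blups[(env, year)] = blup
        cov, cor = genetic_covariance(fit)
        for i, sa in enumerate(fit.site_ids):
            var_rows.append({
                "env": env, "year": year, "site_id": sa,
                "loading": fit.loadings[i, 0] if fit.k_factors == 1 else np.nan,
                "psi": fit.specific_variances[i],
                "var_rep": fit.var_rep, "var_block": fit.var_block,
                "var_genotype": fit.var_genotype, "var_residual": fit.var_residual,
                "reml_loglik": fit.reml_loglik, "converged": fit.converged,
            })
            for j, sb in enumerate(fit.site_ids):
                cov_rows.append({
                    "env": env, "year": year, "site_a": sa, "site_b": sb,
                    "covariance": cov.iloc[i, j], "correlation": cor.iloc[i, j],
                })
        gt = blup.genotype_table.copy()
        gt.insert(0, "env", env)
        gt.insert(1, "year", year)
        gt["lc_mean"] = blup.lc_mean
        blup_rows.append(gt)
        st = blup.site_table.copy()
        st.insert(0, "env", env)
        st.insert(1, "year", year)
        blup_site_rows.append(st)
        _log(config, f"group ({env}, {year}): {len(fit.site_ids)} sites, "
                     f"loglik {fit.reml_loglik:.2f}, converged={fit.converged}")
    if not result.group_fits:
        raise ValueError("no (environment, year) group had enough sites to fit")
    manifest.record_output("variance_components",
                           write_table(pd.DataFrame(var_rows), out / "variance_components.csv"))
    manifest.record_output("genetic_covariances",
                           write_table(pd.DataFrame(cov_rows), out / "genetic_covariances.csv"))
    blups_all = pd.concat(blup_rows, ignore_index=True)
    manifest.record_output("blups", write_table(blups_all, out / "blups.csv"))
    manifest.record_output("blups_by_site",
                           write_table(pd.concat(blup_site_rows, ignore_index=True),
                                       out / "blups_by_site.csv"))
    manifest.record_stage("fa_fits", len(plots_kept), len(result.group_fits))

    # --- stage: gain regressions -------------------------------------------
    gain_rows, hyl_rows, dist_rows = [], [], []
    for env in sorted({e for e, _ in result.group_blups}):
        years = sorted(y for e, y in result.group_blups if e == env)
        gyp_pts, gylc_pts, grand_means = [], [], []
        for year in years:
            blup = result.group_blups[(env, year)]
            sel = select_top_lines(blup, year=year, environment=env, n=config.top_n)
            result.hyl[(env, year)] = sel
            for name, val in zip(sel.genotype_names, sel.blup_means):
                hyl_rows.append({"env": env, "year": year,
                                 "genotype_name": name, "across_site_mean": val})
            gyp_pts.append((year, sel.mean))
            lines = blup.genotype_table.loc[~blup.genotype_table["is_local_check"]]
            grand_means.append(lines["across_site_mean"].mean())
            if np.isfinite(blup.lc_mean) and blup.lc_mean > 0:
                gylc_pts.append((year, sel.mean, blup.lc_mean))
            dist_rows.extend(
                {"env": env, "year": year, "value": v}
                for v in lines["across_site_mean"]
            )
        if len(gyp_pts) >= 2:
            gyp = estimate_gyp_gain(gyp_pts, environment=env,
                                    denominator=config.percent_denominator,
                                    grand_means=grand_means)
            result.gains.append(gyp)
        if len(gylc_pts) >= 2:
            gylc = estimate_gylc_gain(gylc_pts, environment=env)
            result.gains.append(gylc)
    gain_rows = [
        {
            "mode": g.mode, "env": g.environment, "slope": g.slope,
            "slope_kg_per_ha_yr": g.slope_kg_per_ha_yr,
            "percent_rate": g.percent_rate, "intercept": g.intercept,
            "r_squared": g.r_squared, "p_value": g.p_value, "n_years": g.n_years,
        }
        for g in result.gains
    ]
    manifest.record_output("gains", write_table(pd.DataFrame(gain_rows), out / "gains.csv"))
    manifest.record_output("hyl", write_table(pd.DataFrame(hyl_rows), out / "hyl.csv"))
    dist = yearly_yield_distribution(pd.DataFrame(dist_rows)) if dist_rows else pd.DataFrame()
    if len(dist):
        manifest.record_output(
            "yearly_distribution",
            write_table(dist.drop(columns=["density_grid", "density_values"]),
                        out / "yearly_distribution.csv"),
        )
    manifest.record_stage("gains", len(result.group_blups), len(result.gains))
    for g in result.gains:
        _log(config, f"{g.mode} ({g.environment}): {g.slope_kg_per_ha_yr:.1f} kg/ha/yr, "
                     f"{g.percent_rate:.2f} %/yr, p={g.p_value}")

    # --- stage: trait analysis ---------------------------------------------
    env = config.trait_env
    group_years = sorted(y for e, y in result.group_fits if e == env)
    if len(group_years) < 3:
        manifest.warn(f"trait stage skipped: <3 fitted years in {env}")
        manifest.record_stage("traits", len(group_years), 0)
        return
    trait_list = [*config.traits, *(t for t in ("dhm", "gn") if t in plots_kept.columns)]
    records = []
    for year in group_years:
        grp = plots_kept[(plots_kept["env"] == env) & (plots_kept["year"] == year)]
        sel = result.hyl[(env, year)]
        trait_means = {}
        for trait in trait_list:
            if grp[trait].notna().sum() < 2:
                continue
            tfit = reml_fit_fa(grp, trait, config.fa_order, group=(env, year))
            tblup = compute_blups(tfit, grp)
            trait_means[trait] = tblup.genotype_table.set_index("genotype_name")[
                "across_site_mean"
            ]
        for name, gy in zip(sel.genotype_names, sel.blup_means):
            row = {"env": env, "year": year, "genotype_name": name, "gy_t_ha": gy}
            for trait, series in trait_means.items():
                row[trait] = series.get(name, np.nan)
            records.append(row)
    rec = derive_traits(pd.DataFrame(records))
    manifest.record_output("hyl_trait_records", write_table(rec, out / "hyl_trait_records.csv"))

    trend_rows = []
    for trait in [*trait_list, *(t for t in ("dhm", "gn") if t not in trait_list)]:
        if trait not in rec.columns or rec[trait].notna().sum() < 3:
            continue
        yearly = rec.groupby("year")[trait].mean().reset_index().to_numpy()
        tt = trait_trend(yearly, trait=trait)
        tt.pop("flags")
        trend_rows.append(tt)
    trends = pd.DataFrame(trend_rows)
    result.trait_trends = trends
    manifest.record_output("trait_trends", write_table(trends, out / "trait_trends.csv"))

    pred_cols = [c for c in ["gw_mg", "gn", "dm", "dhm", "dh", "ph_cm"] if c in rec.columns]
    model_df = rec[["gy_t_ha", *pred_cols]].dropna()
    if len(model_df) >= len(pred_cols) + 2:
        contrib = sequential_r2(model_df["gy_t_ha"], model_df[pred_cols], order="auto")
        result.trait_contributions = contrib
        tab = contrib.table.copy()
        tab["trait"] = tab["trait"].map(lambda c: TRAIT_LABELS.get(c, c))
        tab["total_r2"] = contrib.total_r2
        manifest.record_output("trait_contributions",
                               write_table(tab, out / "trait_contributions.csv"))
        biplot = biplot_decomposition(model_df[["gy_t_ha", *pred_cols]])
        result.biplot = biplot
        scores = pd.DataFrame(biplot.scores, columns=["dim1", "dim2"])
        loadings = pd.DataFrame(biplot.loadings, columns=["dim1", "dim2"])
        loadings.insert(0, "trait",
                        [TRAIT_LABELS.get(c, c) for c in biplot.trait_names])
        loadings["variance_explained_cum"] = biplot.cumulative
        manifest.record_output("biplot_scores", write_table(scores, out / "biplot_scores.csv"))
        manifest.record_output("biplot_loadings",
                               write_table(loadings, out / "biplot_loadings.csv"))
        _log(config, f"biplot: first two dimensions explain {100 * biplot.cumulative:.1f}%")
    manifest.record_stage("traits", len(group_years), len(trend_rows))
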