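"""Genetic-gain regressions from yearly BLUPs.

Breeding progress is measured two ways: per se (GYP), the regression of the
yearly mean BLUP of the five highest-yielding lines (HYL) on year; and
relative to local checks (GYLC), the regression of
100 * (HYL mean - LC mean) / LC mean on year.  Both are ordinary
least-squares fits; the per se percentage rate divides the slope by the
average yearly HYL mean over the analysed period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GainEstimate",
    "HYLSelection",
    "select_top_lines",
    "estimate_gyp_gain",
    "compute_gylc",
    "estimate_gylc_gain",
    "yearly_yield_distribution",
    "hyl_overlap",
    "environment_correlation",
]


@dataclass
class GainEstimate:
    """One fitted gain regression."""

    mode: str                       # "GYP" or "GYLC"
    environment: str
    slope: float                    # t/ha/yr for GYP; percent points/yr for GYLC
    slope_kg_per_ha_yr: float
    percent_rate: float             # % per year
    intercept: float                # at the mean year
    r_squared: float
    p_value: float | None
    n_years: int
    yearly_points: pd.DataFrame = field(default_factory=pd.DataFrame)
    flags: list = field(default_factory=list)


@dataclass
class HYLSelection:
    """The highest-yielding lines of one year and environment."""

    year: int
    environment: str
    genotype_names: list
    blup_means: np.ndarray
    flags: list = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.blup_means))


def _ols(x: np.ndarray, y: np.ndarray):
    """Centered-year OLS; returns slope, intercept-at-mean-x, r2, p (None if n < 3)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    if np.allclose(xc, 0):
        raise ValueError("need at least two distinct years for a slope")
    sxx = float(xc @ xc)
    slope = float(xc @ y) / sxx
    intercept = float(y.mean())
    resid = y - intercept - slope * xc
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if sst <= 0 else max(0.0, 1.0 - float(resid @ resid) / sst)
    n = len(y)
    if n < 3:
        return slope, intercept, r2, None
    dof = n - 2
    mse = float(resid @ resid) / dof
    if mse <= 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        tstat = slope / np.sqrt(mse / sxx)
        p = float(2 * stats.t.sf(abs(tstat), dof))
    return slope, intercept, r2, p


def select_top_lines(
    blups, year: int | None = None, environment: str = "", n: int = 5
) -> HYLSelection:
    """Pick the n highest non-check lines by across-site predicted mean.

    ``blups`` may be a BlupTable or its genotype-level frame (columns
    genotype_name, across_site_mean, is_local_check).  Ties at the selection
    boundary are broken by genotype name, so the choice is deterministic.
    """
    df = getattr(blups, "genotype_table", blups)
    if year is None:
        year = getattr(blups, "group", ("", 0))[1]
    if not environment:
        environment = str(getattr(blups, "group", ("", 0))[0])
    cand = df.loc[~df["is_local_check"].astype(bool)].copy()
    cand = cand.sort_values(
        ["across_site_mean", "genotype_name"], ascending=[False, True]
    )
    flags = []
    if len(cand) < n:
        flags.append(f"only {len(cand)} candidate lines (requested {n})")
        warnings.warn(flags[-1], stacklevel=2)
    top = cand.head(n)
    return HYLSelection(
        year=int(year),
        environment=environment,
        genotype_names=top["genotype_name"].tolist(),
        blup_means=top["across_site_mean"].to_numpy(float),
        flags=flags,
    )


def estimate_gyp_gain(
    yearly_points, environment: str = "", denominator: str = "hyl_mean",
    grand_means=None,
) -> GainEstimate:
    """Genetic progress per se: OLS of yearly HYL mean yield on year.

    ``yearly_points`` is an iterable of (year, t/ha) pairs.  The percentage
    rate divides the slope by the mean of the yearly HYL means over the
    period ("hyl_mean", default) or by the mean of ``grand_means``
    ("grand_mean").
    """
    pts = pd.DataFrame(list(yearly_points), columns=["year", "value"]).sort_values("year")
    if len(pts) < 2:
        raise ValueError("gain regression needs at least two years")
    slope, intercept, r2, p = _ols(pts["year"], pts["value"])
    if denominator == "hyl_mean":
        denom = float(pts["value"].mean())
    elif denominator == "grand_mean":
        if grand_means is None:
            raise ValueError("grand_mean denominator requires grand_means")
        denom = float(np.mean(grand_means))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    percent = 100.0 * slope / denom if denom > 0 else float("nan")
    return GainEstimate(
        mode="GYP",
        environment=environment,
        slope=slope,
        slope_kg_per_ha_yr=1000.0 * slope,
        percent_rate=percent,
        intercept=intercept,
        r_squared=r2,
        p_value=p,
        n_years=len(pts),
        yearly_points=pts.reset_index(drop=True),
    )


def compute_gylc(hyl_blup_mean: float, lc_mean: float) -> float:
    """Yield advantage over the local checks, percent: 100 (HYL - LC) / LC."""
    if not lc_mean > 0:
        raise ValueError("local-check mean must be positive")
    return 100.0 * (hyl_blup_mean - lc_mean) / lc_mean


def estimate_gylc_gain(yearly, environment: str = "") -> GainEstimate:
    """Gain relative to local checks from (year, hyl_mean, lc_mean) triples.

    The percent series 100 (HYL - LC)/LC is regressed on year for the rate in
    percentage points per year; the absolute difference HYL - LC is regressed
    separately for the slope in kg/ha/yr.  The two slopes are independent
    outputs, not conversions of each other.
    """
    pts = pd.DataFrame(
        list(yearly), columns=["year", "hyl_mean", "lc_mean"]
    ).sort_values("year")
    if len(pts) < 2:
        raise ValueError("gain regression needs at least two years")
    pts["gylc_percent"] = [
        compute_gylc(h, c) for h, c in zip(pts["hyl_mean"], pts["lc_mean"])
    ]
    pts["diff_t_ha"] = pts["hyl_mean"] - pts["lc_mean"]
    slope_pct, intercept, r2, p = _ols(pts["year"], pts["gylc_percent"])
    slope_abs, _, r2_abs, p_abs = _ols(pts["year"], pts["diff_t_ha"])
    est = GainEstimate(
        mode="GYLC",
        environment=environment,
        slope=slope_pct,
        slope_kg_per_ha_yr=1000.0 * slope_abs,
        percent_rate=slope_pct,
        intercept=intercept,
        r_squared=r2,
        p_value=p,
        n_years=len(pts),
        yearly_points=pts.reset_index(drop=True),
    )
    est.flags.append(f"absolute_series: r2={r2_abs:.4f}, p={p_abs}")
    return est


def yearly_yield_distribution(
    blups_by_year: pd.DataFrame, grid_size: int = 256, bandwidth: str | float = "silverman"
) -> pd.DataFrame:
    """Per-year summaries and kernel-density curves of all-line BLUP yields.

    ``blups_by_year`` needs columns year and value (across-site predicted
    means of every line).  Returns one row per year with mean, sd, quantiles
    and density grid/values (None when degenerate).  The default bandwidth is
    Silverman's rule.
    """
    rows = []
    for year, grp in blups_by_year.groupby("year"):
        v = grp["value"].to_numpy(float)
        if len(v) < 5:
            warnings.warn(f"year {year}: fewer than 5 lines", stacklevel=2)
        q = np.quantile(v, [0.05, 0.25, 0.5, 0.75, 0.95]) if len(v) else [np.nan] * 5
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        degenerate = sd <= 0
        if degenerate:
            grid = dens = None
        else:
            kde = stats.gaussian_kde(v, bw_method=bandwidth)
            lo, hi = v.min() - 3 * sd, v.max() + 3 * sd
            grid = np.linspace(lo, hi, grid_size)
            dens = kde(grid)
        rows.append(
            {
                "year": year,
                "n_lines": len(v),
                "mean": float(np.mean(v)),
                "sd": sd,
                "q05": q[0], "q25": q[1], "median": q[2], "q75": q[3], "q95": q[4],
                "degenerate": degenerate,
                "density_grid": grid,
                "density_values": dens,
            }
        )
    return pd.DataFrame(rows)


def hyl_overlap(selection_a: HYLSelection, selection_b: HYLSelection) -> float:
    """Fraction of top lines common to two selections (e.g. two environments)."""
    a, b = set(selection_a.genotype_names), set(selection_b.genotype_names)
    if not a:
        return 0.0
    return len(a & b) / len(a)


def environment_correlation(
    table_a: pd.DataFrame, table_b: pd.DataFrame, method: str = "pearson"
) -> float:
    """Correlation of line predictions between two environments.

    Computed on the genotypes common to both genotype-level BLUP frames.
    """
    merged = table_a.merge(table_b, on="genotype_name", suffixes=("_a", "_b"))
    merged = merged.loc[
        ~(merged["is_local_check_a"].astype(bool) | merged["is_local_check_b"].astype(bool))
    ]
    if len(merged) < 3:
        return float("nan")
    return float(
        merged["across_site_mean_a"].corr(merged["across_site_mean_b"], method=method)
    )
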