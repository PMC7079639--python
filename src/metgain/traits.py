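"""Physiological-trait analysis: derived traits, trends, contribution to yield.

Secondary traits are derived from their components (grain-filling duration
DHM = DM - DH; grain number GN = yield / single-grain weight), yearly trend
rates of the top lines' trait means are estimated by OLS, and the
association of yield with its component traits is decomposed two ways: a
correlation biplot from the SVD of the standardized trait matrix, and a
sequential partial-R2 decomposition of a multiple linear regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gains import _ols

__all__ = [
    "TraitContributionTable",
    "BiplotResult",
    "derive_traits",
    "trait_trend",
    "sequential_r2",
    "biplot_decomposition",
]


@dataclass
class TraitContributionTable:
    """Sequential partial-R2 decomposition of a yield regression."""

    table: pd.DataFrame          # trait, cumulative_r2, partial_r2, contribution_pct
    total_r2: float
    coefficients: pd.Series      # full-model coefficients incl. intercept
    p_values: pd.Series
    order: list
    collinear: bool = False
    flags: list = field(default_factory=list)


@dataclass
class BiplotResult:
    """Two-dimensional biplot coordinates from an SVD."""

    scores: np.ndarray           # (n_obs, 2)
    loadings: np.ndarray         # (n_traits, 2)
    trait_names: list
    variance_explained: np.ndarray   # fractions per retained dimension
    cumulative: float
    all_fractions: np.ndarray
    flags: list = field(default_factory=list)


def derive_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Add derived traits to a record table.

    dhm = dm - dh (grain-filling duration, days); gn = grain number per m2
    from yield in g/m2 and single-grain weight in mg; gy_t_ha from gy_g_m2
    when absent.  Rows with missing or invalid components keep NaN in the
    derived column but are retained for the other traits; invalid rows are
    flagged in the derived_flags column.
    """
    df = records.copy()
    flags = pd.Series([""] * len(df), index=df.index)
    if "dhm" not in df and "dh" in df and "dm" in df:
        df["dhm"] = df["dm"] - df["dh"]
        bad = df["dhm"].notna() & (df["dhm"] < 0)
        if bad.any():
            flags[bad] += "dhm_invalid(dm<=dh);"
            df.loc[bad, "dhm"] = np.nan
    if "gy_g_m2" not in df and "gy_t_ha" in df:
        df["gy_g_m2"] = 100.0 * df["gy_t_ha"]
    if "gy_t_ha" not in df and "gy_g_m2" in df:
        df["gy_t_ha"] = 0.01 * df["gy_g_m2"]
    if "gn" not in df and "gw_mg" in df and "gy_g_m2" in df:
        gw_g = df["gw_mg"] / 1000.0
        valid = gw_g > 0
        df["gn"] = np.where(valid, df["gy_g_m2"] / gw_g, np.nan)
        bad = df["gw_mg"].notna() & ~valid
        if bad.any():
            flags[bad] += "gn_missing(gw<=0);"
    df["derived_flags"] = flags
    return df


def trait_trend(yearly_means, trait: str = "") -> dict:
    """OLS trend of a trait's yearly top-line means.

    ``yearly_means`` is an iterable of (year, value) pairs.  Returns slope
    (trait units per year), p_value (None with fewer than 3 years, flagged),
    r_squared, n_years.
    """
    pts = pd.DataFrame(list(yearly_means), columns=["year", "value"]).dropna()
    pts = pts.sort_values("year")
    if len(pts) < 2:
        raise ValueError("trait trend needs at least two years")
    slope, intercept, r2, p = _ols(pts["year"], pts["value"])
    flags = []
    if len(pts) < 3:
        flags.append("fewer than 3 years: no p-value")
        warnings.warn(f"trait {trait or '?'}: {flags[0]}", stacklevel=2)
    return {
        "trait": trait,
        "slope": slope,
        "intercept": intercept,
        "p_value": p,
        "r_squared": r2,
        "n_years": len(pts),
        "flags": flags,
    }


def _prefix_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R2 of an intercept-included least-squares fit (min-norm under collinearity)."""
    n = len(y)
    Z = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0:
        return 0.0
    return 1.0 - float(resid @ resid) / sst


def sequential_r2(
    response, predictors: pd.DataFrame, order="auto"
) -> TraitContributionTable:
    """Decompose a multiple regression's R2 into sequential trait contributions.

    The partial R2 of the t-th trait in the order is the increase in R2 when
    it joins the first t-1; these telescope to the full-model R2.  With
    ``order="auto"`` the order is greedy forward selection by incremental R2
    (ties broken by trait name).  Exact collinearity is detected and flagged;
    the collinear trait's partial is then whatever it adds on the residual
    space (typically ~0).
    """
    y = np.asarray(response, float)
    X = predictors.astype(float)
    names = sorted(X.columns) if order == "auto" else list(order)
    if len(y) < X.shape[1] + 2:
        raise ValueError("need at least 2 more observations than predictors")
    if (X.std(ddof=0) <= 0).any():
        const = list(X.columns[X.std(ddof=0) <= 0])
        raise ValueError(f"constant predictor(s): {const}")

    flags = []
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X.to_numpy()]))
    collinear = rank < X.shape[1] + 1
    if collinear:
        flags.append("exact collinearity among predictors; pivoting on residual space")
        warnings.warn(flags[-1], stacklevel=2)

    if order == "auto":
        chosen: list[str] = []
        remaining = sorted(X.columns)
        r2_prev = 0.0
        while remaining:
            gains = []
            for c in remaining:
                r2c = _prefix_r2(y, X[chosen + [c]].to_numpy())
                gains.append((-(r2c - r2_prev), c, r2c))
            gains.sort()
            _, best, r2_best = gains[0]
            chosen.append(best)
            remaining.remove(best)
            r2_prev = r2_best
        names = chosen
    else:
        missing = set(names) - set(X.columns)
        if missing:
            raise ValueError(f"order names not in predictors: {sorted(missing)}")

    rows = []
    r2_prev = 0.0
    for t, name in enumerate(names, start=1):
        r2_t = _prefix_r2(y, X[names[:t]].to_numpy())
        rows.append((name, r2_t, r2_t - r2_prev))
        r2_prev = r2_t
    total = r2_prev
    table = pd.DataFrame(rows, columns=["trait", "cumulative_r2", "partial_r2"])
    table["contribution_pct"] = (
        100.0 * table["partial_r2"] / total if total > 0 else 0.0
    )

    model = sm.OLS(y, sm.add_constant(X[names].to_numpy())).fit()
    idx = ["intercept"] + names
    coefficients = pd.Series(model.params, index=idx)
    p_values = pd.Series(model.pvalues, index=idx)
    return TraitContributionTable(
        table=table,
        total_r2=float(total),
        coefficients=coefficients,
        p_values=p_values,
        order=names,
        collinear=collinear,
        flags=flags,
    )


def biplot_decomposition(trait_matrix: pd.DataFrame) -> BiplotResult:
    """Correlation biplot of observations and traits via SVD.

    Columns are standardized to zero mean and unit variance (traits have
    incommensurate units), the SVD is taken, and the singular values are
    split evenly between observation scores and trait loadings.  Variance
    explained per dimension is the squared singular value over their total.
    """
    df = trait_matrix.astype(float).dropna()
    if df.shape[0] < 3 or df.shape[1] < 2:
        raise ValueError("biplot needs >= 3 observations and >= 2 traits")
    M = df.to_numpy()
    sd = M.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("constant trait column cannot be standardized")
    Z = (M - M.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    frac = s**2 / float(np.sum(s**2))
    flags = []
    if np.linalg.matrix_rank(Z) < 2:
        flags.append("rank<2: second dimension carries no variance")
        warnings.warn(flags[-1], stacklevel=2)
    scores = U[:, :2] * np.sqrt(s[:2])
    loadings = Vt[:2].T * np.sqrt(s[:2])
    return BiplotResult(
        scores=scores,
        loadings=loadings,
        trait_names=list(df.columns),
        variance_explained=frac[:2],
        cumulative=float(frac[:2].sum()),
        all_fractions=frac,
        flags=flags,
    )
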