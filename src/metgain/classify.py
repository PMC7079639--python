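"""Climate-based environment classification of trial sites.

Sites are grouped by k-means on standardized climate covariates
(precipitation and mean minimum temperature of the coolest quarter, and
altitude), then the cluster with the higher mean precipitation is labelled
the high-rainfall environment.  A 150 mm precipitation rule is used as a
per-site consistency check on the labelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["EnvAssignment", "classify_sites", "label_clusters", "PRECIP_THRESHOLD_MM"]

#: Precipitation rule separating high- from low-rainfall environments (mm).
PRECIP_THRESHOLD_MM = 150.0

DEFAULT_COVARIATES = (
    "precip_coolest_quarter_mm",
    "tmin_mean_coolest_C",
    "altitude_m",
)


@dataclass
class EnvAssignment:
    """Cluster assignment of sites, with centres in original units."""

    assignments: pd.DataFrame            # site_id, cluster, label, threshold_consistent
    centers: pd.DataFrame                # one row per cluster, original units
    inertia: float                       # within-cluster sum of squares (standardized)
    restarts: int
    covariates: list = field(default_factory=list)
    labeled: bool = False
    warnings_: list = field(default_factory=list)


def classify_sites(
    climate: pd.DataFrame,
    k: int = 2,
    restarts: int = 25,
    seed: int = 0,
    covariates=DEFAULT_COVARIATES,
) -> EnvAssignment:
    """Cluster sites on standardized climate covariates with restarted k-means.

    The best of ``restarts`` initialisations by within-cluster sum of squares
    is kept; results are deterministic for a fixed seed.  Constant covariates
    are dropped with a warning.  Raises if there are fewer sites than
    clusters or no informative covariates remain.
    """
    df = climate.drop_duplicates(subset="site_id").reset_index(drop=True)
    if len(df) < k:
        raise ValueError(f"need at least k={k} sites, got {len(df)}")
    used, warns = [], []
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"climate table lacks covariate {cov!r}")
        if df[cov].std(ddof=0) <= 0:
            warns.append(f"constant covariate {cov!r} dropped")
            warnings.warn(warns[-1], stacklevel=2)
        else:
            used.append(cov)
    if not used:
        raise ValueError(
            "all covariates are constant: cannot form distinct clusters"
        )
    M = df[list(used)].to_numpy(float)
    mu, sd = M.mean(axis=0), M.std(axis=0, ddof=0)
    Z = (M - mu) / sd
    if len(np.unique(Z, axis=0)) < k:
        raise ValueError("fewer distinct sites than clusters")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(seed) % (2**32))
    cluster = km.fit_predict(Z)
    centers = pd.DataFrame(km.cluster_centers_ * sd + mu, columns=used)
    centers.insert(0, "cluster", np.arange(k))
    assignments = pd.DataFrame(
        {"site_id": df["site_id"], "cluster": cluster, "label": [""] * len(df)}
    )
    return EnvAssignment(
        assignments=assignments,
        centers=centers,
        inertia=float(km.inertia_),
        restarts=restarts,
        covariates=list(used),
        warnings_=warns,
    )


def label_clusters(assignment: EnvAssignment, climate: pd.DataFrame) -> EnvAssignment:
    """Attach semantic labels: higher mean precipitation -> high_rainfall.

    Ties on mean precipitation are broken by altitude (the lower-altitude
    cluster becomes low_rainfall, with a warning).  Each site is checked
    against the 150 mm precipitation rule and flagged when its label
    disagrees.  Idempotent: relabelling an already labelled assignment gives
    the same result.
    """
    if assignment.assignments["cluster"].nunique() != 2:
        raise ValueError("semantic labelling requires exactly two clusters")
    df = assignment.assignments.drop(columns=["label", "threshold_consistent"], errors="ignore")
    merged = df.merge(
        climate.drop_duplicates("site_id")[["site_id", "precip_coolest_quarter_mm", "altitude_m"]],
        on="site_id",
        how="left",
    )
    means = merged.groupby("cluster")["precip_coolest_quarter_mm"].mean()
    warns = list(assignment.warnings_)
    if np.isclose(means.iloc[0], means.iloc[1]):
        alts = merged.groupby("cluster")["altitude_m"].mean()
        low_cluster = int(alts.idxmin())
        warns.append(
            "equal mean precipitation between clusters; tie broken by altitude"
        )
        warnings.warn(warns[-1], stacklevel=2)
    else:
        low_cluster = int(means.idxmin())
    label_map = {
        c: ("low_rainfall" if c == low_cluster else "high_rainfall")
        for c in means.index
    }
    merged["label"] = merged["cluster"].map(label_map)
    merged["threshold_consistent"] = np.where(
        merged["label"] == "high_rainfall",
        merged["precip_coolest_quarter_mm"] >= PRECIP_THRESHOLD_MM,
        merged["precip_coolest_quarter_mm"] < PRECIP_THRESHOLD_MM,
    )
    out = merged[["site_id", "cluster", "label", "threshold_consistent"]]
    centers = assignment.centers.copy()
    centers["label"] = centers["cluster"].map(label_map)
    return EnvAssignment(
        assignments=out,
        centers=centers,
        inertia=assignment.inertia,
        restarts=assignment.restarts,
        covariates=assignment.covariates,
        labeled=True,
        warnings_=warns,
    )
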