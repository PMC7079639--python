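"""Readers, writers and the run manifest.

All tabular I/O is comma-separated text with a header row; numbers are
serialized at 10 significant digits so that re-reading reproduces values to
that precision and checksums are stable across platforms.  The plot-table
reader validates the schema and cross-checks the two yield unit columns.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "REQUIRED_PLOT_COLUMNS",
    "read_plot_table",
    "read_climate_table",
    "write_table",
    "sha256_file",
    "RunManifest",
]

REQUIRED_PLOT_COLUMNS = [
    "year",
    "site_id",
    "rep",
    "block",
    "entry",
    "genotype_name",
    "is_local_check",
]
TRAIT_COLUMNS = ["gy_g_m2", "gy_t_ha", "gw_mg", "dh", "dm", "ph_cm", "dhm", "gn"]
#: g/m2 -> t/ha conversion factor.
G_M2_TO_T_HA = 0.01
FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as CSV at the documented serialization precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_plot_table(path, rel_tol: float = 1e-6, abs_tol: float = 1e-6):
    """Read and validate a long-format plot table.

    Returns ``(plots, report)``.  Required identifier columns must be
    present; at least one trait column must be present.  Rows whose numeric
    fields fail to parse are dropped and counted; rows where gy_g_m2 and
    gy_t_ha disagree with the x0.01 conversion are kept but flagged.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "genotype_name": str})
    missing = [c for c in REQUIRED_PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plot table missing required column(s): {missing}")
    traits = [c for c in TRAIT_COLUMNS if c in df.columns]
    if not traits:
        raise ValueError("plot table has no trait column")
    report = {"n_rows_read": len(df), "n_rows_dropped": 0,
              "n_inconsistent_yield": 0, "warnings": []}
    if df.empty:
        report["warnings"].append("empty plot table")
        return df, report

    n0 = len(df)
    for col in ["year", "rep", "block", "entry", "is_local_check"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in traits:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["year", "rep", "block", "entry", "is_local_check"]].isna().any(axis=1)
    if bad.any():
        report["warnings"].append(f"{int(bad.sum())} row(s) with unparseable ids dropped")
    df = df.loc[~bad].copy()
    report["n_rows_dropped"] = n0 - len(df)
    for col in ["year", "rep", "block", "entry", "is_local_check"]:
        df[col] = df[col].astype(int)

    if "gy_g_m2" in df.columns and "gy_t_ha" in df.columns:
        both = df["gy_g_m2"].notna() & df["gy_t_ha"].notna()
        expect = G_M2_TO_T_HA * df.loc[both, "gy_g_m2"]
        diff = (df.loc[both, "gy_t_ha"] - expect).abs()
        inconsistent = diff > (abs_tol + rel_tol * expect.abs())
        df["yield_consistent"] = True
        df.loc[both[both].index[inconsistent], "yield_consistent"] = False
        n_bad = int(inconsistent.sum())
        report["n_inconsistent_yield"] = n_bad
        if n_bad:
            report["warnings"].append(
                f"{n_bad} row(s) with inconsistent gy_g_m2 / gy_t_ha"
            )
    return df.reset_index(drop=True), report


def read_climate_table(path):
    """Read a per-site climate covariate table."""
    df = pd.read_csv(path, dtype={"site_id": str})
    required = ["site_id", "precip_coolest_quarter_mm", "tmin_mean_coolest_C", "altitude_m"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"climate table missing required column(s): {missing}")
    if (df["precip_coolest_quarter_mm"] < 0).any():
        raise ValueError("negative precipitation in climate table")
    implausible = (df["altitude_m"] < -500) | (df["altitude_m"] > 9000)
    if implausible.any():
        raise ValueError("implausible altitude (outside -500..9000 m)")
    return df


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class RunManifest:
    """Reproducibility record of one pipeline run."""

    def __init__(self, config_snapshot: dict, version: str, seed: int):
        self.data = {
            "software": {"name": "metgain", "version": version},
            "config": config_snapshot,
            "seed": seed,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": [],
            "outputs": {},
            "warnings": [],
            "completed": False,
        }

    def record_stage(self, name: str, n_in: int, n_out: int, **extra) -> None:
        self.data["stages"].append(
            {"stage": name, "n_in": int(n_in), "n_out": int(n_out), **extra}
        )

    def record_output(self, label: str, path) -> None:
        self.data["outputs"][label] = {
            "path": str(path),
            "sha256": sha256_file(path),
        }

    def warn(self, message: str) -> None:
        self.data["warnings"].append(str(message))

    def finish(self, completed: bool = True) -> None:
        self.data["completed"] = bool(completed)
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)

        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        path.write_text(yaml.safe_dump(_clean(self.data), sort_keys=False))
        return path
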