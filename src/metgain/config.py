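"""Configuration containers for the simulator and the full analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

# Default climate centres: (precipitation of the coolest quarter in mm,
# mean minimum temperature of the coolest quarter in °C, altitude in m)
# for the high- and low-rainfall environment groups.
HIGH_RAINFALL_CENTER = (282.0, 9.34, 781.0)
LOW_RAINFALL_CENTER = (53.0, 9.87, 329.0)


@dataclass
class SimulationConfig:
    """Generating conditions for a synthetic multi-year international nursery.

    Defaults emulate a high-rainfall wheat yield trial series: 50 entries per
    annual nursery (one local check per site), an alpha-lattice with two
    replicates and five incomplete blocks per replicate, a linear genetic
    trend of 0.16 t/ha/yr among new elite entries, local checks improving
    0.0949 t/ha/yr (so elite lines pull ahead of checks by ~65 kg/ha/yr),
    and a factor-analytic site covariance for genotype-by-environment
    deviations.  Variance components are in (t/ha)^2.
    """

    n_years: int = 10
    entries_per_year: int = 50          # includes the local-check slot
    n_sites_per_year: int = 8
    n_reps: int = 2
    n_blocks_per_rep: int = 5
    true_annual_gain: float = 0.16      # t/ha per year, new-entry mean shift
    baseline_yield: float = 4.0         # t/ha, first-year elite mean
    fa_loadings: object = None          # scalar, (S,) or (S, k); None -> graded default
    fa_specific_vars: object = 0.05     # scalar or (S,)
    var_genotype: float = 0.2
    var_rep: float = 0.03
    var_block: float = 0.03
    var_residual: float = 0.16
    env_mix: float = 0.577              # fraction of high-rainfall sites
    climate_centers: tuple = (HIGH_RAINFALL_CENTER, LOW_RAINFALL_CENTER)
    climate_spread: tuple = (30.0, 1.2, 120.0)
    local_check_lag: float = 0.6        # t/ha below the current elite mean
    lc_annual_gain: float = 0.0949      # t/ha per year improvement of checks
    trait_trends: dict = field(
        default_factory=lambda: {"gw_mg": 1.08, "dm": 4.10, "dh": 0.0, "ph_cm": 0.0}
    )
    site_effect_sd: float = 0.4         # t/ha spread of site main effects
    env_site_shift: float = 0.3         # t/ha bonus of high-rainfall sites
    first_year: int = 15                # nursery cycle index of the first year
    seed: int = 0

    def validate(self) -> None:
        for name in ("var_genotype", "var_rep", "var_block", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.env_mix <= 1.0:
            raise ValueError("env_mix must be in [0, 1]")
        if self.entries_per_year < 2:
            raise ValueError("entries_per_year must be >= 2")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.n_sites_per_year < 1:
            raise ValueError("at least one site per year is required")
        if self.n_years < 1:
            raise ValueError("at least one year is required")
        if self.n_blocks_per_rep < 1:
            raise ValueError("n_blocks_per_rep must be >= 1")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "climate_centers" in data:
            data["climate_centers"] = tuple(tuple(c) for c in data["climate_centers"])
        if "climate_spread" in data:
            data["climate_spread"] = tuple(data["climate_spread"])
        return cls(**data)


@dataclass
class RunConfig:
    """Settings of one end-to-end pipeline run."""

    plot_table: str = ""
    climate_table: str = ""
    out_dir: str = "metgain_out"
    traits: list = field(default_factory=lambda: ["gw_mg", "dh", "dm", "ph_cm"])
    yield_trait: str = "gy_t_ha"
    h2_threshold: float = 0.05
    kmeans_k: int = 2
    kmeans_restarts: int = 25
    seed: int = 0
    fa_order: int = 1
    top_n: int = 5
    percent_denominator: str = "hyl_mean"   # or "grand_mean"
    trait_env: str = "high_rainfall"        # environment used for trait analyses
    min_sites_per_group: int = 2
    verbosity: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.h2_threshold <= 1.0:
            raise ValueError("h2_threshold must be in [0, 1]")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.percent_denominator not in {"hyl_mean", "grand_mean"}:
            raise ValueError("percent_denominator must be 'hyl_mean' or 'grand_mean'")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
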