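"""Synthetic multi-environment trial generator with known ground truth.

Emulates the structure of an international wheat yield nursery: a fixed set
of testing locations, each contributing every year; each year a fresh set of
elite entries plus the location's own local check, grown in an alpha-lattice
with replicated incomplete blocks; a built-in linear genetic trend across
years among new entries; and a factor-analytic genotype-by-site covariance.
Local checks are site-specific commercial varieties: one check identity per
site, whose quality improves smoothly over years as collaborators replace
varieties.  Because every generating quantity is recorded in a
:class:`SimulationTruth`, downstream estimators can be validated by
parameter recovery instead of against undeposited field data.

All randomness flows from a single seed through named substreams (design,
genetics, climate, residual, traits) so stages can be regenerated
independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = ["SimulationTruth", "simulate_program", "generate_site_climate"]

#: Genotype-level baselines of the physiological traits (units of the trait).
TRAIT_BASES = {"gw_mg": 38.0, "dm": 115.0, "dh": 68.0, "ph_cm": 85.0}
#: Between-genotype standard deviation of each trait.
TRAIT_GENETIC_SD = {"gw_mg": 2.5, "dm": 3.0, "dh": 3.0, "ph_cm": 5.0}
#: Plot-level measurement noise standard deviation.
TRAIT_RESID_SD = {"gw_mg": 1.5, "dm": 2.0, "dh": 2.0, "ph_cm": 4.0}
#: Correlation of each trait's genotype effect with the yield genetic
#: deviation; grain weight and maturity load positively on the yield trend
#: so trait-contribution analyses have signal to find.  Arbitrary choices.
TRAIT_YIELD_CORR = {"gw_mg": 0.5, "dm": 0.4, "dh": 0.1, "ph_cm": 0.0}

_STREAMS = ("design", "genetics", "climate", "residual", "traits")


@dataclass
class SimulationTruth:
    """Generating quantities of one simulated program."""

    genetic_values: pd.DataFrame      # genotype_name, year, true_value, is_local_check
    site_labels: pd.DataFrame         # site_id, env_true
    site_params: pd.DataFrame         # site_id, loadings..., psi
    site_effects: pd.DataFrame        # site_id, year, effect
    true_gain: float
    lc_gain: float
    variance_components: dict
    notes: list = field(default_factory=list)

    def sigma_s(self, site_ids) -> np.ndarray:
        """True site covariance Lam Lam' + diag(psi) for the given sites."""
        sub = self.site_params.set_index("site_id").loc[list(site_ids)]
        lam_cols = [c for c in sub.columns if c.startswith("lam")]
        lam = sub[lam_cols].to_numpy(float)
        return lam @ lam.T + np.diag(sub["psi"].to_numpy(float))


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def generate_site_climate(
    n_sites: int,
    env_mix: float = 0.577,
    centers=None,
    spread=(30.0, 1.2, 120.0),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    site_ids=None,
) -> pd.DataFrame:
    """Draw site climate covariates around two environment centres.

    Each site is assigned to the high-rainfall group with probability
    ``env_mix`` and its (precipitation, minimum temperature, altitude)
    triplet is drawn around the corresponding centre with the given
    per-variable standard deviations.  The returned frame carries the
    generating label in ``env_true``.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    spread = np.asarray(spread, dtype=float)
    if np.any(spread < 0):
        raise ValueError("spread must be nonnegative")
    if centers is None:
        from .config import HIGH_RAINFALL_CENTER, LOW_RAINFALL_CENTER
        centers = (HIGH_RAINFALL_CENTER, LOW_RAINFALL_CENTER)
    high, low = (np.asarray(c, dtype=float) for c in centers)
    if rng is None:
        rng = np.random.default_rng(seed)
    is_high = rng.random(n_sites) < env_mix
    base = np.where(is_high[:, None], high[None, :], low[None, :])
    vals = base + rng.normal(size=(n_sites, 3)) * spread[None, :]
    vals[:, 0] = np.maximum(vals[:, 0], 0.0)        # precipitation >= 0
    if site_ids is None:
        site_ids = [f"S{i + 1:03d}" for i in range(n_sites)]
    return pd.DataFrame(
        {
            "site_id": list(site_ids),
            "precip_coolest_quarter_mm": vals[:, 0],
            "tmin_mean_coolest_C": vals[:, 1],
            "altitude_m": vals[:, 2],
            "env_true": np.where(is_high, "high_rainfall", "low_rainfall"),
        }
    )


def _loading_matrix(config: SimulationConfig) -> np.ndarray:
    """Per-site loading matrix (S, k) from the configured value."""
    S = config.n_sites_per_year
    lam = config.fa_loadings
    if lam is None:
        # graded loadings across sites: heterogeneous but smooth GE structure
        lam = np.linspace(0.3, 0.8, S)
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if lam.ndim == 1:
        if lam.size == 1:
            lam = np.full(S, float(lam[0]))
        if lam.size != S:
            raise ValueError("fa_loadings length must equal n_sites_per_year")
        lam = lam[:, None]
    elif lam.shape[0] != S:
        raise ValueError("fa_loadings must have one row per site")
    return lam


def _specific_vector(config: SimulationConfig) -> np.ndarray:
    psi = np.atleast_1d(np.asarray(config.fa_specific_vars, dtype=float))
    if psi.size == 1:
        psi = np.full(config.n_sites_per_year, float(psi[0]))
    if psi.size != config.n_sites_per_year:
        raise ValueError("fa_specific_vars length must equal n_sites_per_year")
    if np.any(psi < 0):
        raise ValueError("fa_specific_vars must be nonnegative")
    return psi


def _block_sizes(n_entries: int, n_blocks: int, notes: list) -> list[int]:
    base, rem = divmod(n_entries, n_blocks)
    if base == 0:
        n_blocks = n_entries
        base, rem = 1, 0
    sizes = [base] * n_blocks
    for i in range(rem):
        sizes[i] += 1
    if rem and not notes:
        notes.append(
            f"entries_per_year={n_entries} not divisible into {n_blocks} blocks; "
            f"block sizes adjusted to {sizes}"
        )
    return sizes


def simulate_program(config: SimulationConfig):
    """Simulate a full multi-year program.

    Returns ``(plot_table, climate_table, truth)``.  The plot table is in
    long format, one row per plot, with grain yield both in g/m2 and t/ha
    and the physiological traits GW, DH, DM and PH; the climate table has
    one row per site; the truth object records every generating quantity.
    """
    config.validate()
    rngs = _rngs(config.seed)
    lam_mat = _loading_matrix(config)
    psi_vec = _specific_vector(config)
    k = lam_mat.shape[1]
    E = config.entries_per_year
    n_elite = E - 1
    S = config.n_sites_per_year
    notes: list[str] = []
    sizes = _block_sizes(E, config.n_blocks_per_rep, notes)
    sd_g = np.sqrt(config.var_genotype)

    # --- persistent sites: climate, environment label, local check --------
    site_ids = [f"S{j + 1:02d}" for j in range(S)]
    climate = generate_site_climate(
        S,
        config.env_mix,
        config.climate_centers,
        config.climate_spread,
        rng=rngs["climate"],
        site_ids=site_ids,
    )
    env_is_high = (climate["env_true"] == "high_rainfall").to_numpy()
    lc_names = [f"LC-{sid}" for sid in site_ids]
    # one check identity per site; its base quality is drawn once and its
    # year-to-year improvement (variety replacement) is smooth
    lc_base = (
        config.baseline_yield
        - config.local_check_lag
        + rngs["genetics"].normal(0.0, sd_g, S)
    )
    lc_fscores = rngs["genetics"].normal(size=(S, k))

    plot_rows = []
    gv_rows = []
    site_effect_rows = []

    for t in range(config.n_years):
        year = config.first_year + t
        elite_mean = config.baseline_yield + config.true_annual_gain * t
        elite_names = [f"HW{year}-{i + 1:03d}" for i in range(n_elite)]
        g_elite = elite_mean + rngs["genetics"].normal(0.0, sd_g, n_elite)
        g_lc = lc_base + config.lc_annual_gain * t

        all_names = elite_names + lc_names
        g_all = np.concatenate([g_elite, g_lc])
        f_scores = np.vstack(
            [rngs["genetics"].normal(size=(n_elite, k)), lc_fscores]
        )
        name_index = {n: i for i, n in enumerate(all_names)}

        # seasonal site quality: environment bonus plus a fresh yearly draw
        site_eff = (
            np.where(env_is_high, config.env_site_shift, 0.0)
            + rngs["design"].normal(0.0, config.site_effect_sd, S)
        )
        for sid, e in zip(site_ids, site_eff):
            site_effect_rows.append((sid, year, e))
        for name, g in zip(all_names, g_all):
            gv_rows.append((name, year, g, name.startswith("LC-")))

        # genotype-level trait values (shared across sites within the year)
        g_dev = (g_all - g_all.mean()) / (sd_g if sd_g > 0 else 1.0)
        trait_geno = {}
        for tr, base in TRAIT_BASES.items():
            rho = TRAIT_YIELD_CORR[tr]
            sd_t = TRAIT_GENETIC_SD[tr]
            trend = config.trait_trends.get(tr, 0.0)
            z = rngs["traits"].normal(size=len(all_names))
            trait_geno[tr] = (
                base + trend * t + rho * sd_t * g_dev + np.sqrt(1 - rho**2) * sd_t * z
            )

        for j, sid in enumerate(site_ids):
            # site-specific genetic deviations for every genotype
            ge = f_scores @ lam_mat[j] + rngs["genetics"].normal(
                0.0, np.sqrt(psi_vec[j]), len(all_names)
            )
            entry_names = elite_names + [lc_names[j]]   # LC occupies entry E
            rep_eff = rngs["design"].normal(0.0, np.sqrt(config.var_rep), config.n_reps)
            for r in range(config.n_reps):
                perm = rngs["design"].permutation(E)
                blk_eff = rngs["design"].normal(
                    0.0, np.sqrt(config.var_block), len(sizes)
                )
                pos = 0
                for b, size in enumerate(sizes):
                    for entry_idx in perm[pos : pos + size]:
                        name = entry_names[entry_idx]
                        gi = name_index[name]
                        resid = rngs["residual"].normal(0.0, np.sqrt(config.var_residual))
                        y = site_eff[j] + rep_eff[r] + blk_eff[b] + g_all[gi] + ge[gi] + resid
                        row = {
                            "year": year,
                            "site_id": sid,
                            "rep": r + 1,
                            "block": b + 1,
                            "entry": int(entry_idx) + 1,
                            "genotype_name": name,
                            "is_local_check": int(name.startswith("LC-")),
                            "gy_g_m2": 100.0 * y,
                            "gy_t_ha": y,
                        }
                        for tr in TRAIT_BASES:
                            row[tr] = trait_geno[tr][gi] + rngs["traits"].normal(
                                0.0, TRAIT_RESID_SD[tr]
                            )
                        plot_rows.append(row)
                    pos += size

    plot_table = pd.DataFrame(plot_rows)
    climate_table = climate
    lam_cols = [f"lam{i + 1}" for i in range(k)]
    truth = SimulationTruth(
        genetic_values=pd.DataFrame(
            gv_rows, columns=["genotype_name", "year", "true_value", "is_local_check"]
        ),
        site_labels=climate[["site_id", "env_true"]].copy(),
        site_params=pd.DataFrame(
            {
                "site_id": site_ids,
                **{c: lam_mat[:, i] for i, c in enumerate(lam_cols)},
                "psi": psi_vec,
            }
        ),
        site_effects=pd.DataFrame(
            site_effect_rows, columns=["site_id", "year", "effect"]
        ),
        true_gain=config.true_annual_gain,
        lc_gain=config.lc_annual_gain,
        variance_components={
            "var_genotype": config.var_genotype,
            "var_rep": config.var_rep,
            "var_block": config.var_block,
            "var_residual": config.var_residual,
        },
        notes=notes,
    )
    if notes:
        warnings.warn(notes[0], stacklevel=2)
    return plot_table, climate_table, truth
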