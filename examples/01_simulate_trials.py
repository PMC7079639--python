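"""Generate a synthetic international yield-trial series with known truth.

Builds a 5-year program (30 entries per nursery, 6 sites, alpha-lattice with
two replicates) and prints its dimensions and the generating quantities that
downstream examples try to recover.
"""

from metgain import SimulationConfig, simulate_program

config = SimulationConfig(n_years=5, entries_per_year=30, n_sites_per_year=6, seed=1)
plots, climate, truth = simulate_program(config)

print(f"plots: {len(plots)} rows "
      f"({plots['year'].nunique()} years x {plots['site_id'].nunique()} sites x "
      f"{config.entries_per_year} entries x {config.n_reps} reps)")
print(f"sites by environment: {climate['env_true'].value_counts().to_dict()}")
print(f"generating per se gain: {truth.true_gain} t/ha/yr; "
      f"check improvement: {truth.lc_gain} t/ha/yr")
print(f"variance components: {truth.variance_components}")
print("true site genetic covariance (first 3 sites):")
print(truth.sigma_s(climate['site_id'][:3]).round(3))
# Yield units: plots carry both g/m2 and t/ha; the mixed models use t/ha.
print(plots[["year", "site_id", "genotype_name", "gy_g_m2", "gy_t_ha"]].head(3))
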