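import numpy as np
import pandas as pd
import pytest

from metgain import SimulationConfig, simulate_program


@pytest.fixture(scope="session")
def small_program():
    """A small but structured multi-year program used by several suites."""
    cfg = SimulationConfig(
        n_years=4, entries_per_year=20, n_sites_per_year=4, seed=42
    )
    plots, climate, truth = simulate_program(cfg)
    return cfg, plots, climate, truth


@pytest.fixture()
def one_site_plots():
    """Balanced single-site two-replicate data with genetic signal, no blocks."""
    rng = np.random.default_rng(7)
    g, r = 30, 2
    geno = np.tile(np.arange(g), r)
    rep = np.repeat(np.arange(1, r + 1), g)
    gvals = rng.normal(0, np.sqrt(0.6), g)
    y = 4.0 + 0.3 * (rep - 1) + gvals[geno] + rng.normal(0, np.sqrt(0.3), g * r)
    return pd.DataFrame(
        {
            "year": 15,
            "site_id": "S01",
            "rep": rep,
            "block": 1,
            "entry": geno + 1,
            "genotype_name": [f"G{i:02d}" for i in geno],
            "is_local_check": 0,
            "gy_t_ha": y,
        }
    )


def make_fa_group(
    rng,
    n_sites=4,
    n_geno=20,
    n_reps=2,
    n_blocks=2,
    lam=None,
    psi=None,
    sig2_g=0.2,
    sig2_rep=0.03,
    sig2_block=0.03,
    sig2_e=0.16,
    mu=4.0,
):
    """Hand-rolled single-group dataset with known factor-analytic truth.

    Independent of the package generator: used where a test needs direct
    control over one group's covariance structure.
    """
    lam = np.zeros(n_sites) if lam is None else np.asarray(lam, float)
    psi = np.zeros(n_sites) if psi is None else np.asarray(psi, float)
    f = rng.normal(size=n_geno)
    gmain = rng.normal(0, np.sqrt(sig2_g), n_geno)
    delta = rng.normal(size=(n_sites, n_geno)) * np.sqrt(psi)[:, None]
    site_eff = rng.normal(0, 0.3, n_sites)
    rows = []
    for s in range(n_sites):
        rep_eff = rng.normal(0, np.sqrt(sig2_rep), n_reps)
        for r in range(n_reps):
            perm = rng.permutation(n_geno)
            blocks = np.array_split(perm, n_blocks)
            blk_eff = rng.normal(0, np.sqrt(sig2_block), n_blocks)
            for b, members in enumerate(blocks):
                for i in members:
                    y = (
                        mu + site_eff[s] + rep_eff[r] + blk_eff[b]
                        + gmain[i] + lam[s] * f[i] + delta[s, i]
                        + rng.normal(0, np.sqrt(sig2_e))
                    )
                    rows.append(
                        {
                            "year": 15,
                            "site_id": f"S{s + 1:02d}",
                            "rep": r + 1,
                            "block": b + 1,
                            "entry": i + 1,
                            "genotype_name": f"G{i:02d}",
                            "is_local_check": int(i == n_geno - 1),
                            "gy_t_ha": y,
                        }
                    )
    truth = {
        "sigma_s": np.outer(lam, lam) + np.diag(psi),
        "gmain": gmain,
        "total_genetic": np.outer(lam, lam) + np.diag(psi) + sig2_g,
        "sig2_g": sig2_g,
        "sig2_e": sig2_e,
    }
    return pd.DataFrame(rows), truth
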