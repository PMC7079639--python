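# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `metgain`.

## The analysis chain

The package analyses an international nursery series the way such networks
are analysed in practice: every site-year is screened individually, the
surviving sites are grouped by climate, each (environment, year) group is
fitted with a multi-site mixed model whose genotype-by-site covariance is
factor-analytic, and breeding progress is read off regressions of the top
lines' predicted yields on year.

### Per-site model and heritability screen

For one site, plot yield is modelled as

    Y_ijk = mu + R_j + B_k(R_j) + G_i + e_ijk,

replicates and genotypes fixed, incomplete blocks within replicates random
with variance `sigma2_b`, residuals iid `sigma2_e`.  This parameterisation
gives the adjusted genotype means.  Heritability needs a genotype variance,
which a fixed-genotype model does not provide, so the site is refitted with
genotypes random (same block structure) solely to obtain `sigma2_g`; the
dual fit keeps both requirements consistent.  The reported heritability is
the entry-mean form

    H2 = sigma2_g / (sigma2_g + sigma2_e / r),

with `r` the replicate count; a plot-basis variant
(`sigma2_g / (sigma2_g + sigma2_b + sigma2_e)`) is selectable.  Sites with
H2 below 0.05 are excluded (strict inequality: the boundary site is kept).
The screen is a data-quality filter, not a hypothesis test; its operating
characteristics at 50 entries x 2 replicates are discussed under
Limitations.

### Environment classification

Retained sites are clustered by k-means (k = 2 by default, 25 restarts,
seeded) on standardized covariates: precipitation and mean minimum
temperature of the coolest quarter, and altitude.  Standardization makes
the clustering invariant to affine rescaling of any covariate.  The cluster
with the higher mean precipitation is labelled `high_rainfall`; ties are
broken by altitude.  Each site is additionally checked against the 150 mm
precipitation rule and flagged when its cluster label disagrees — the flag
reports, it does not overrule the clustering.

### Multi-site factor-analytic model

Each (environment, year) group is fitted with

    y = 1 mu + X_s s + Z_r r + Z_b b + Z_g g + Z_ge ge + e,

sites fixed; replicates-within-site, blocks-within-replicate, genotype main
effects and residuals independent with scalar variances; and the
genotype-by-site term with covariance `Sigma_s (x) I_g`, where
`Sigma_s = Lam Lam' + Psi` is a factor-analytic site matrix of order k
(default k = 1, selectable; AIC/BIC are reported for comparison).  Local
checks enter as ordinary genotype levels under their site-qualified names.

REML maximises the restricted log-likelihood with L-BFGS-B on transformed
parameters — log variances (so nonnegativity is automatic and boundary
estimates collapse cleanly to zero) and unconstrained loadings, with the
upper-right triangle of `Lam` pinned to zero for k > 1 (rotation
identification) and the first nonzero loading of each factor canonicalised
positive (sign identification).  Gradients are analytic; the response is
standardized internally so any measurement units are equally well
conditioned, and results are back-transformed (the fit is exactly
scale-equivariant).  Starting values come from a moment decomposition of
the genotype-by-site cell-mean covariance: the median off-diagonal seeds
the genotype main variance and the leading eigenvectors of the remainder
seed the loadings.  This matters because a genotype main variance and a
constant loading vector produce identical covariance contributions — the
two are only jointly identified, and the moment start places the optimiser
on the data-supported side of that ridge.  Convergence: relative
log-likelihood change below 1e-8 or 300 iterations; non-convergence returns
the best iterate, flagged.

Predictions solve Henderson's mixed-model equations at the fitted
variances, with the genotype-by-site block covering every (site, genotype)
cell — lines are therefore predicted at sites where they were not grown,
through the fitted between-site covariance.  Zero-variance terms are
dropped (fully shrunk); singular systems fall back to the minimum-norm
solution with a warning.  Between-site genetic correlations include the
main-effect variance: `corr(i,j) = (sigma2_g + Sigma_s[i,j]) /
sqrt((sigma2_g + Sigma_s[i,i])(sigma2_g + Sigma_s[j,j]))`.

### Gains

Within each group-year, the five highest-yielding non-check lines (HYL) by
across-site predicted mean are selected; ties at the boundary break by
genotype name so reruns are identical.  GYP regresses the yearly HYL mean
on the nursery-year index (centered at its mean; slopes are invariant to
the centering) and reports t/ha/yr, kg/ha/yr (x1000) and percent per year
relative to the period-average HYL mean (a grand-mean denominator is
selectable).  GYLC regresses 100 (HYL - LC)/LC for the rate in percentage
points per year, and the absolute margin HYL - LC for the kg/ha/yr slope —
two regressions on their own series, never converted into each other.

The local-check benchmark LC is, by default, the observed mean yield of the
checks across all their plots in the group.  A shrunk variant (the mean of
the checks' predicted across-site values) is computed alongside
(`lc_predicted_mean`).  The observed mean is the default because each check
is grown at a single site: BLUP shrinkage pulls such entries strongly
toward the group mean, which systematically attenuates the year trend of
the check benchmark and hence inflates nothing but damps the GYLC slope by
tens of percent; the unshrunk mean is trend-unbiased.

### Traits

Days from heading to maturity (DHM = DM - DH) and grain number
(GN = yield in g/m2 divided by single-grain weight in g) are derived at
plot level and then modelled exactly like measured traits — each trait gets
its own factor-analytic fit and BLUPs per group-year.  Trend rates are OLS
slopes of the yearly HYL trait means.  The yield association is decomposed
two ways: sequential partial R² of the multiple regression of yield on the
traits (partial R² of the t-th trait = R² gain when it joins the first
t-1; the greedy forward order is the default, and the partials telescope
exactly to the total R²), and a correlation biplot (SVD of the
column-standardized trait matrix, singular values split evenly between
scores and loadings).  Exact collinearity (e.g. DH, DM and DHM together)
is detected and flagged; the collinear trait contributes only what survives
on the residual space.

## The synthetic-data generator

The generator emulates the structure of a high-rainfall nursery series:

- **Persistent locations.** A fixed set of sites participates every year;
  each has one climate record and one standing local-check variety.  The
  check's quality improves smoothly at `lc_annual_gain` (variety turnover
  by the cooperator), starting `local_check_lag` below the elite mean.
- **Annual entry turnover.** Every year brings a fresh elite set whose mean
  genetic value advances by `true_annual_gain`; entries never recur.
- **Design.** Alpha-lattice: per (site, replicate) the entries are randomly
  partitioned into `n_blocks_per_rep` incomplete blocks (the last block
  absorbs any remainder, recorded in the truth notes); two replicates.
- **Genotype-by-site structure.** Each genotype carries factor scores; site
  j adds `lam_j . f_i` plus a site-specific deviation with variance
  `psi_j`, so the between-site genetic covariance is exactly
  `Lam Lam' + Psi`.
- **Traits.** GW, DH, DM and PH are genotype-level values with configured
  annual trends plus plot noise; grain weight and maturity are positively
  correlated with the yield genetic deviation (module constants, documented
  as arbitrary) so contribution analyses have signal.  Yield is emitted in
  g/m2 with the t/ha companion column.
- **Seeding.** One seed feeds named substreams (design, genetics, climate,
  residual, traits); identical seeds give bit-identical tables.

Defaults are chosen once as realistic values for an elite spring-wheat
network and used as the study conditions throughout the tests: baseline
elite mean 4.0 t/ha; per se trend 0.16 t/ha/yr with check improvement
0.0949 t/ha/yr (so the margin over checks grows by 65 kg/ha/yr); plot
residual variance 0.16 (t/ha)² (a ~10 % CV), genotype variance 0.2
(entry-mean H2 ~ 0.7 at two replicates), replicate and block variances
0.03; graded loadings 0.3–0.8 t/ha with specific variances 0.05 (GE
comparable to the main genetic variance, as is typical across diverse
sites); 57.7 % of sites high-rainfall, climate centres (282 mm, 9.34 °C,
781 m) and (53 mm, 9.87 °C, 329 m); trait trends +1.08 mg/yr (GW),
+4.10 d/yr (DM), flat DH and PH.

What the generator does **not** emulate — and therefore what passing
recovery tests do not establish about field data: spatial field trend
within trials, missing or failed plots, year-to-year participation changes,
disease epidemics, pedigree relatedness among entries (genotypes are iid),
heterogeneous residual variances across sites, and measurement error models
for the physiological traits beyond iid noise.

## Problem sizes in the test suite

Recovery experiments are run at desk scale, chosen as the smallest sizes at
which the estimators' sampling noise still leaves the stated tolerances
meaningful: the factor-analytic recovery uses 20 single-year groups of
8 sites x 40 entries x 2 replicates; the gain and trait-trend recoveries
share one batch of 50 ten-year programs of 4 sites x 24 entries x 2
replicates (high-rainfall only); the acceptance script re-runs the
trait-trend chain on the same program dimensions.

## Numerical choices

- Variance parameters live on the log scale, bounded at exp(-18) (an
  effective zero, reported as 0) and exp(12) after internal response
  standardization.
- Negative variance estimates cannot occur (boundary REML); specific
  variances at the boundary are flagged.
- The site covariance is regularised before inversion in the prediction
  equations only when numerically singular, by a jitter scaled to its
  trace.
- Serialized tables round to 10 significant digits; re-reading reproduces
  values to that precision, and manifests record SHA-256 checksums.
- Adjusted means from a rank-deficient fixed design (e.g. a genotype in one
  replicate) fall back to the minimum-norm least-squares solution, flagged.

## Known limitations

- **H2 screen under the null.** With 50 entries and 2 replicates the
  entry-mean H2 estimate of a site with zero genotype variance exceeds
  0.05 roughly 40–60 % of the time — the null sampling spread of
  `sigma2_g_hat` is scale-free and only narrows around g ~ thousands of
  entries.  The screen therefore reliably keeps good sites but only
  partially removes signal-free ones; at real-world trial dimensions no
  estimator variant changes this materially.
- **Weak identifiability of `sigma2_g` vs a constant loading.** The
  default model keeps both terms; only their sum is well identified.
  Comparisons of fitted and generating covariances should use the total
  genetic covariance `sigma2_g + Sigma_s`, as the tests do.  A pure-FA
  option (`include_main_effect=False`) collapses the main effect into
  `Sigma_s`.
- **Shrunk check benchmarks.** The BLUP-based check mean is attenuated for
  one-site entries (see Gains); it is reported but not used for the GYLC
  trend by default.
- A single residual variance is fitted across the sites of a group;
  site-heterogeneous residuals are a known extension not implemented.
- No spatial (row-column) adjustment within sites.
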