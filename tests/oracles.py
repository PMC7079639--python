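"""Independent reference implementations used only to check the package.

These deliberately take the slow, direct route: dense marginal-covariance
GLS for mixed-model predictions, expected-mean-squares ANOVA for balanced
variance components, and refit-every-prefix partial R2.  They share no code
path with the implementations they validate.
"""

from __future__ import annotations

import numpy as np


def gls_oracle(y, X, Z_blocks, G_blocks, sig2_e):
    """Fixed effects and BLUPs by direct inversion of the marginal covariance.

    Z_blocks: list of design matrices; G_blocks: matching covariance blocks.
    Returns (beta, [u_1, u_2, ...]).
    """
    y = np.asarray(y, float)
    n = len(y)
    V = sig2_e * np.eye(n)
    for Z, G in zip(Z_blocks, G_blocks):
        V = V + Z @ G @ Z.T
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.pinv(XtVinvX) @ (X.T @ Vinv @ y)
    resid = y - X @ beta
    us = [G @ Z.T @ Vinv @ resid for Z, G in zip(Z_blocks, G_blocks)]
    return beta, us


def anova_balanced(y, geno, rep):
    """Expected-mean-squares estimates for a balanced genotype x replicate layout.

    Model: fixed mean and replicate, random genotype, residual.  Returns
    (sig2_g, sig2_e) from MS_G = sig2_e + r sig2_g and MSE.
    """
    y = np.asarray(y, float)
    genos = np.unique(geno)
    reps = np.unique(rep)
    g, r = len(genos), len(reps)
    gm = y.mean()
    ybar_g = np.array([y[geno == gg].mean() for gg in genos])
    ybar_r = np.array([y[rep == rr].mean() for rr in reps])
    ms_g = r * np.sum((ybar_g - gm) ** 2) / (g - 1)
    fitted = (
        ybar_g[np.searchsorted(genos, geno)]
        + ybar_r[np.searchsorted(reps, rep)]
        - gm
    )
    mse = np.sum((y - fitted) ** 2) / ((g - 1) * (r - 1))
    return (ms_g - mse) / r, mse


def prefix_r2_oracle(y, X_df, order):
    """Partial R2 by refitting the regression for every prefix of the order."""
    y = np.asarray(y, float)
    out = []
    prev = 0.0
    for t in range(1, len(order) + 1):
        M = np.column_stack([np.ones(len(y)), X_df[order[:t]].to_numpy(float)])
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ beta
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / sst
        out.append(r2 - prev)
        prev = r2
    return np.array(out), prev


def ols_oracle(x, y):
    """Closed-form simple regression with the classical t-test p-value."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc = x - x.mean()
    slope = float(xc @ y) / float(xc @ xc)
    intercept = y.mean() - slope * 0.0  # intercept at the mean of x
    resid = y - y.mean() - slope * xc
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    se = np.sqrt(float(resid @ resid) / (n - 2) / float(xc @ xc))
    p = 2 * stats.t.sf(abs(slope / se), n - 2) if se > 0 else 0.0
    return slope, intercept, r2, p
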