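"""Dense REML machinery for variance-component and factor-analytic mixed models.

This module implements the linear mixed model

    y = X b + sum_t Z_t u_t [+ Z_ge ge] + e

where each ``u_t`` is an iid random term with covariance ``sig2_t I`` and the
optional ``ge`` term carries a genotype-by-environment covariance
``Sigma_s (x) I_g`` with a factor-analytic site matrix
``Sigma_s = Lam Lam' + diag(psi)``.  Estimation maximises the restricted
(residual) log-likelihood with analytic gradients on transformed parameters
(log variances, unconstrained loadings); prediction solves Henderson's
mixed-model equations at fixed variance parameters.

Everything is dense: the intended problem sizes are single sites or small
groups of sites (hundreds to a few thousand plots), where dense Cholesky
factorisations are fast and far easier to audit than sparse formulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "IIDTerm",
    "FATerm",
    "REMLResult",
    "MMESolution",
    "reml_fit",
    "solve_mme",
    "fa_covariance",
]

_LOG_VAR_LO = -18.0  # effectively a zero variance on the log scale
_LOG_VAR_HI = 12.0
_PSI_FLOOR = 1e-10


@dataclass
class IIDTerm:
    """A random term u ~ N(0, sig2 * I) entering through a level-indicator design.

    ``codes`` holds the 0-based level index of each observation; ``n_levels``
    may exceed ``codes.max() + 1`` when some levels are unobserved.
    """

    name: str
    codes: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.intp)
        if self.codes.size and self.codes.max() >= self.n_levels:
            raise ValueError(f"term {self.name!r}: code exceeds n_levels")

    def design(self, n: int) -> np.ndarray:
        Z = np.zeros((n, self.n_levels))
        Z[np.arange(n), self.codes] = 1.0
        return Z


@dataclass
class FATerm:
    """Genotype-by-site interaction with site covariance Lam Lam' + diag(psi).

    The latent effect vector is indexed by (site, genotype) cells, site-major,
    so its covariance is the Kronecker product of the site matrix with an
    identity over genotypes.
    """

    site_codes: np.ndarray
    geno_codes: np.ndarray
    n_sites: int
    n_geno: int
    k: int = 1

    def __post_init__(self) -> None:
        self.site_codes = np.asarray(self.site_codes, dtype=np.intp)
        self.geno_codes = np.asarray(self.geno_codes, dtype=np.intp)
        if self.k < 1:
            raise ValueError("FA order k must be >= 1")
        if self.k >= self.n_sites:
            raise ValueError("FA order k must be smaller than the number of sites")

    @property
    def n_cells(self) -> int:
        return self.n_sites * self.n_geno

    def cell_codes(self) -> np.ndarray:
        return self.site_codes * self.n_geno + self.geno_codes

    def design(self, n: int) -> np.ndarray:
        Z = np.zeros((n, self.n_cells))
        Z[np.arange(n), self.cell_codes()] = 1.0
        return Z

    def loading_mask(self) -> np.ndarray:
        """Boolean (n_sites, k) mask of free loadings (upper-right triangle pinned at 0)."""
        mask = np.ones((self.n_sites, self.k), dtype=bool)
        for j in range(1, self.k):
            mask[:j, j] = False
        return mask


def fa_covariance(loadings: np.ndarray, specific: np.ndarray) -> np.ndarray:
    """Site covariance Sigma_s = Lam Lam' + diag(psi) of a factor-analytic model."""
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    if loadings.shape[0] == 1 and np.asarray(specific).size > 1:
        loadings = loadings.T
    return loadings @ loadings.T + np.diag(np.asarray(specific, dtype=float))


@dataclass
class REMLResult:
    """REML estimate of all variance parameters of one model."""

    variances: dict[str, float]
    residual_variance: float
    loadings: np.ndarray | None
    specific_variances: np.ndarray | None
    loglik: float
    n_iterations: int
    converged: bool
    grad_norm: float
    message: str = ""
    fixed_effects: np.ndarray | None = None
    history: list[float] = field(default_factory=list)

    def site_covariance(self) -> np.ndarray | None:
        if self.loadings is None:
            return None
        return fa_covariance(self.loadings, self.specific_variances)


class _REMLProblem:
    """Precomputed masks and the REML objective/gradient for one dataset."""

    def __init__(self, y, X, iid_terms, fa_term):
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        self.n = n
        X = np.atleast_2d(np.asarray(X, dtype=float))
        # reduce X to a full-column-rank basis so the restricted likelihood is defined
        q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, abs(r[0, 0]))))
        self.X = X[:, np.sort(piv[:rank])]
        self.rank_x = rank
        self.iid_terms = list(iid_terms)
        self.fa_term = fa_term
        self.masks = [
            t.codes[:, None] == t.codes[None, :] for t in self.iid_terms
        ]
        if fa_term is not None:
            self.geno_mask = fa_term.geno_codes[:, None] == fa_term.geno_codes[None, :]
            self.site_ind = np.zeros((n, fa_term.n_sites))
            self.site_ind[np.arange(n), fa_term.site_codes] = 1.0
            self.free = fa_term.loading_mask()
            self.n_load = int(self.free.sum())
        else:
            self.n_load = 0
        self.n_iid = len(self.iid_terms)

    # --- parameter packing -------------------------------------------------
    # theta = [log sig2 per iid term, log sig2_e, free loadings, log psi]

    def n_params(self) -> int:
        extra = self.n_load + (self.fa_term.n_sites if self.fa_term else 0)
        return self.n_iid + 1 + extra

    def unpack(self, theta):
        sig2 = np.exp(theta[: self.n_iid])
        sig2_e = float(np.exp(theta[self.n_iid]))
        lam = psi = None
        if self.fa_term is not None:
            S, k = self.fa_term.n_sites, self.fa_term.k
            lam = np.zeros((S, k))
            off = self.n_iid + 1
            lam[self.free] = theta[off : off + self.n_load]
            psi = np.exp(theta[off + self.n_load :])
        return sig2, sig2_e, lam, psi

    def build_v(self, sig2, sig2_e, lam, psi):
        V = np.full((self.n, self.n), 0.0)
        np.fill_diagonal(V, sig2_e)
        for s2, mask in zip(sig2, self.masks):
            V += s2 * mask
        if self.fa_term is not None:
            Sigma = lam @ lam.T + np.diag(psi)
            si = self.fa_term.site_codes
            V += Sigma[np.ix_(si, si)] * self.geno_mask
        return V

    def neg_loglik_grad(self, theta):
        sig2, sig2_e, lam, psi = self.unpack(theta)
        V = self.build_v(sig2, sig2_e, lam, psi)
        try:
            L, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
        Vinv = linalg.cho_solve((L, low), np.eye(self.n), check_finite=False)
        VinvX = Vinv @ self.X
        XtVinvX = self.X.T @ VinvX
        sign, logdet_x = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            return np.inf, np.zeros_like(theta)
        beta = np.linalg.solve(XtVinvX, VinvX.T @ self.y)
        P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
        Py = P @ self.y
        quad = float(self.y @ Py)
        loglik = -0.5 * (logdet_v + logdet_x + quad)

        grad = np.zeros_like(theta)
        # iid terms: dV/dlog sig2 = sig2 * mask
        for i, (s2, mask, term) in enumerate(zip(sig2, self.masks, self.iid_terms)):
            tr = float(np.sum(P * mask))
            s = np.bincount(term.codes, weights=Py, minlength=term.n_levels)
            grad[i] = 0.5 * s2 * (float(s @ s) - tr)
        # residual
        grad[self.n_iid] = 0.5 * sig2_e * (float(Py @ Py) - np.trace(P))
        if self.fa_term is not None:
            ft = self.fa_term
            PG = P * self.geno_mask
            T = self.site_ind.T @ PG @ self.site_ind
            # R[g, s] = sum of Py over the (site, genotype) cell
            R = np.zeros((ft.n_geno, ft.n_sites))
            np.add.at(R, (ft.geno_codes, ft.site_codes), Py)
            Q = R.T @ R
            D = Q - T
            g_lam = D @ lam              # (S, k); d l / d lam
            g_psi = 0.5 * psi * np.diag(D)
            off = self.n_iid + 1
            grad[off : off + self.n_load] = g_lam[self.free]
            grad[off + self.n_load :] = g_psi
        self._last = (beta, loglik)
        return -loglik, -grad


def _default_start(problem: _REMLProblem) -> np.ndarray:
    """Starting values: split the OLS residual variance evenly across terms.

    When a factor-analytic term is present, the loadings and specific
    variances are seeded from a moment decomposition of the genotype-by-site
    cell-mean covariance, which places the start on the right side of the
    weakly identified ridge between the genotype main variance and a
    constant-loading factor.
    """
    y, X = problem.y, problem.X
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(y.size - problem.rank_x, 1)
    s2 = float(resid @ resid) / dof
    s2 = max(s2, 1e-6)
    theta = np.empty(problem.n_params())
    if problem.fa_term is None:
        share = s2 / (problem.n_iid + 1)
        theta[:] = np.log(share)
        return theta

    ft = problem.fa_term
    S, k = ft.n_sites, ft.k
    # genotype-by-site cell means of OLS residuals
    M = np.full((S, ft.n_geno), np.nan)
    cnt = np.zeros((S, ft.n_geno))
    tot = np.zeros((S, ft.n_geno))
    np.add.at(cnt, (ft.site_codes, ft.geno_codes), 1.0)
    np.add.at(tot, (ft.site_codes, ft.geno_codes), resid)
    obs = cnt > 0
    M[obs] = tot[obs] / cnt[obs]
    # pooled within-cell variance approximates residual + rep/block noise
    ss_within = float(resid @ resid) - float(np.nansum(cnt * np.where(obs, M, 0.0) ** 2))
    df_within = max(int(cnt.sum() - obs.sum()), 1)
    s2_e0 = max(ss_within / df_within, 0.05 * s2)
    rbar = max(float(cnt[obs].mean()), 1.0)
    # pairwise-complete covariance of cell means across genotypes
    Mc = M - np.nanmean(M, axis=1, keepdims=True)
    Z = np.where(np.isnan(Mc), 0.0, Mc)
    O = obs.astype(float)
    npair = O @ O.T
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (Z @ Z.T) / np.maximum(npair - 1.0, 1.0)
    C = np.where(npair >= 3, C, 0.0)
    off_mask = ~np.eye(S, dtype=bool)
    has_geno_term = any(
        np.array_equal(t.codes, ft.geno_codes) and t.n_levels == ft.n_geno
        for t in problem.iid_terms
    )
    offdiag = C[off_mask]
    s2_g0 = float(np.median(offdiag)) if offdiag.size else 0.0
    s2_g0 = max(s2_g0, 1e-3 * s2) if has_geno_term else 0.0
    A = C - s2_g0
    np.fill_diagonal(A, np.diag(C) - s2_g0 - s2_e0 / rbar)
    A = 0.5 * (A + A.T)
    w, V = np.linalg.eigh(A)
    idx = np.argsort(w)[::-1][:k]
    lam = V[:, idx] * np.sqrt(np.maximum(w[idx], 1e-4 * s2))
    # honour the rotation constraint of the parameterisation
    lam_full = np.zeros((S, k))
    lam_full[problem.free] = lam[problem.free]
    psi0 = np.maximum(np.diag(A) - np.sum(lam_full**2, axis=1), 0.02 * s2)

    for i, t in enumerate(problem.iid_terms):
        if has_geno_term and np.array_equal(t.codes, ft.geno_codes):
            theta[i] = np.log(max(s2_g0, 1e-4 * s2))
        else:
            theta[i] = np.log(0.1 * s2)
    theta[problem.n_iid] = np.log(max(s2_e0 - 0.2 * s2, 0.4 * s2_e0))
    off = problem.n_iid + 1
    theta[off : off + problem.n_load] = lam_full[problem.free]
    theta[off + problem.n_load :] = np.log(psi0)
    return theta


def reml_fit(
    y,
    X,
    iid_terms: list[IIDTerm],
    fa_term: FATerm | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 300,
    tol: float = 1e-8,
    gtol: float = 1e-7,
) -> REMLResult:
    """Maximise the restricted log-likelihood of a variance-component model.

    Parameters are optimised on a transformed scale (log variances,
    unconstrained loadings) with L-BFGS-B and analytic gradients, which keeps
    variances nonnegative and lets boundary estimates collapse to zero.
    The first nonzero loading of each factor is canonicalised to be positive
    (the likelihood is invariant to sign flips of a loading column).
    """
    y = np.asarray(y, dtype=float)
    # standardize the response internally: keeps the optimizer well conditioned
    # for any measurement units, and makes the fit exactly scale-equivariant
    scale = float(np.std(y))
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0
    problem = _REMLProblem(y / scale, X, iid_terms, fa_term)
    if start is None:
        theta0 = _default_start(problem)
    else:
        theta0 = np.asarray(start, dtype=float).copy()
        n_var = problem.n_iid + 1
        theta0[:n_var] -= 2.0 * np.log(scale)
        if fa_term is not None:
            theta0[n_var : n_var + problem.n_load] /= scale
            theta0[n_var + problem.n_load :] -= 2.0 * np.log(scale)
    n_var = problem.n_iid + 1
    bounds = [(_LOG_VAR_LO, _LOG_VAR_HI)] * n_var
    if fa_term is not None:
        bounds += [(-100.0, 100.0)] * problem.n_load
        bounds += [(_LOG_VAR_LO, _LOG_VAR_HI)] * fa_term.n_sites
    res = optimize.minimize(
        problem.neg_loglik_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": gtol},
    )
    # re-evaluate at the optimum so loglik and fixed effects match res.x
    nll_final, grad_final = problem.neg_loglik_grad(res.x)
    sig2, sig2_e, lam, psi = problem.unpack(res.x)
    # zero out variances that ran to the lower boundary of the log scale
    sig2 = np.where(sig2 < 2e-8, 0.0, sig2)
    if sig2_e < 2e-8:
        sig2_e = 0.0
    if lam is not None:
        psi = np.where(psi < 2e-8, 0.0, psi)
        for j in range(lam.shape[1]):
            nz = np.flatnonzero(np.abs(lam[:, j]) > 1e-9)
            if nz.size and lam[nz[0], j] < 0:
                lam[:, j] = -lam[:, j]
    variances = {t.name: float(s2) * scale**2 for t, s2 in zip(iid_terms, sig2)}
    beta = getattr(problem, "_last", (None, None))[0]
    if beta is not None:
        beta = beta * scale
    if lam is not None:
        lam = lam * scale
        psi = psi * scale**2
    # restricted likelihood of the unscaled data
    loglik = float(-nll_final) - (problem.n - problem.rank_x) * np.log(scale)
    return REMLResult(
        variances=variances,
        residual_variance=float(sig2_e) * scale**2,
        loadings=lam,
        specific_variances=psi,
        loglik=loglik,
        n_iterations=int(res.nit),
        converged=bool(res.success),
        grad_norm=float(np.max(np.abs(grad_final))),
        message=str(res.message),
        fixed_effects=beta,
    )


def reml_loglik(y, X, iid_terms, fa_term, variances, residual_variance,
                loadings=None, specific_variances=None) -> float:
    """Restricted log-likelihood at given (untransformed) variance parameters."""
    problem = _REMLProblem(y, X, iid_terms, fa_term)
    theta = np.empty(problem.n_params())
    theta[: problem.n_iid] = np.log(np.maximum(
        [variances[t.name] for t in problem.iid_terms], 1e-300))
    theta[problem.n_iid] = np.log(max(residual_variance, 1e-300))
    if fa_term is not None:
        lam = np.atleast_2d(np.asarray(loadings, float))
        if lam.shape[0] == 1 and fa_term.n_sites > 1:
            lam = lam.T
        off = problem.n_iid + 1
        theta[off : off + problem.n_load] = lam[problem.free]
        theta[off + problem.n_load :] = np.log(
            np.maximum(np.asarray(specific_variances, float), 1e-300))
    nll, _ = problem.neg_loglik_grad(theta)
    return -nll


@dataclass
class MMESolution:
    """Solution of Henderson's mixed-model equations at fixed variances."""

    fixed_effects: np.ndarray
    fixed_names: list[str]
    random_effects: dict[str, np.ndarray]
    prediction_error_var: dict[str, np.ndarray]
    singular: bool = False


def solve_mme(
    y,
    X,
    iid_terms: list[IIDTerm],
    variances: dict[str, float],
    residual_variance: float,
    fa_term: FATerm | None = None,
    loadings=None,
    specific_variances=None,
    fixed_names: list[str] | None = None,
) -> MMESolution:
    """Solve the mixed-model equations, returning BLUEs and BLUPs.

    The GE block covers every (site, genotype) cell, observed or not, so
    unobserved combinations are predicted through the site covariance.
    A singular coefficient matrix falls back to the minimum-norm solution.
    Zero-variance random terms are shrunk entirely to zero.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    sig2_e = max(float(residual_variance), 1e-12)

    blocks: list[tuple[str, np.ndarray, np.ndarray]] = []  # (name, Z, Ginv*sig2_e)
    dropped: list[tuple[str, int]] = []
    for t in iid_terms:
        s2 = float(variances[t.name])
        if s2 <= 0:
            dropped.append((t.name, t.n_levels))
            continue
        blocks.append((t.name, t.design(n), (sig2_e / s2) * np.eye(t.n_levels)))
    if fa_term is not None:
        Sigma = fa_covariance(loadings, specific_variances)
        # regularise only when near-singular (psi at the boundary), scaled to
        # the matrix so any measurement units work
        eigs = np.linalg.eigvalsh(Sigma) if Sigma.size else np.array([0.0])
        eps = max(1e-8 * float(np.trace(Sigma)) / fa_term.n_sites, _PSI_FLOOR)
        if eigs.min() <= eps:
            Sigma = Sigma + eps * np.eye(fa_term.n_sites)
        if np.allclose(Sigma, 0.0):
            dropped.append(("ge", fa_term.n_cells))
        else:
            Sinv = np.linalg.inv(Sigma)
            Ginv = np.kron(Sinv, np.eye(fa_term.n_geno)) * sig2_e
            blocks.append(("ge", fa_term.design(n), Ginv))

    q = sum(Z.shape[1] for _, Z, _ in blocks)
    W = np.hstack([X] + [Z for _, Z, _ in blocks]) if blocks else X
    C = W.T @ W
    off = p
    for _, Z, Ginv in blocks:
        m = Z.shape[1]
        C[off : off + m, off : off + m] += Ginv
        off += m
    rhs = W.T @ y

    singular = False
    try:
        sol = linalg.solve(C, rhs, assume_a="sym")
        if not np.all(np.isfinite(sol)):
            raise linalg.LinAlgError
        # guard against a numerically singular but "solvable" system
        if np.linalg.norm(C @ sol - rhs) > 1e-6 * max(1.0, np.linalg.norm(rhs)):
            raise linalg.LinAlgError
    except linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(C, rhs, rcond=None)
        singular = True

    beta = sol[:p]
    random_effects: dict[str, np.ndarray] = {}
    pev: dict[str, np.ndarray] = {}
    if blocks:
        if singular:
            Cinv_diag = np.diag(np.linalg.pinv(C))
        else:
            try:
                Cinv_diag = np.diag(linalg.inv(C))
            except linalg.LinAlgError:
                singular = True
                Cinv_diag = np.diag(np.linalg.pinv(C))
        off = p
        for name, Z, _ in blocks:
            m = Z.shape[1]
            random_effects[name] = sol[off : off + m]
            pev[name] = sig2_e * np.maximum(Cinv_diag[off : off + m], 0.0)
            off += m
    for name, m in dropped:
        random_effects[name] = np.zeros(m)
        pev[name] = np.zeros(m)
    return MMESolution(
        fixed_effects=beta,
        fixed_names=fixed_names or [f"b{i}" for i in range(p)],
        random_effects=random_effects,
        prediction_error_var=pev,
        singular=singular,
    )
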