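"""Pedigree-aware association models for age acceleration and risk factors.

The analysis model treats each risk factor as the outcome, with chronological
age, sex, and one acceleration measure (intrinsic or extrinsic) as fixed
effects and an additive polygenic random effect whose covariance is the
pedigree relationship matrix A (the animal model):

    y = X beta + a + e,   a ~ N(0, sigma_a^2 A),   e ~ N(0, sigma_e^2 I)

Gaussian outcomes are fitted by REML (profiled over the variance ratio via an
eigendecomposition of A, which diagonalises the covariance); binary outcomes
by a latent-liability probit Gibbs sampler with the residual variance fixed
at one. Numeric variables are z-scored before fitting and multiple testing is
controlled by Bonferroni within each acceleration measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MethylAccelError, Pedigree
from .synthetic import RISK_FACTORS

DEFAULT_M_TESTS = 12
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Additive relationship matrix (tabular method)
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrix:
    """Expected additive relationships (2x kinship), pedigree order."""

    ids: pd.Index
    A: np.ndarray

    def __post_init__(self) -> None:
        if self.A.shape != (len(self.ids), len(self.ids)):
            raise MethylAccelError("relationship matrix shape does not match ids")
        if not np.allclose(self.A, self.A.T):
            raise MethylAccelError("relationship matrix must be symmetric")
        if np.any(np.diag(self.A) < 1.0 - 1e-12):
            raise MethylAccelError("relationship diagonal must be >= 1")

    def reorder(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = pd.Index(ids)
        lookup = {i: k for k, i in enumerate(self.ids)}
        perm = np.array([lookup[i] for i in idx])
        return RelationshipMatrix(ids=idx, A=self.A[np.ix_(perm, perm)])


def build_relationship_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Tabular method: A_ii = 1 + A(sire,dam)/2; A_ij = (A(j,sire_i) + A(j,dam_i))/2,
    with unknown parents contributing zero."""
    pedigree.validate()  # also rejects cycles via the ordering requirement
    t = pedigree.table
    ids = pd.Index(t["individual_id"])
    n = len(ids)
    pos = {ind: k for k, ind in enumerate(ids)}

    def parent_pos(p):
        return None if (p is None or pd.isna(p)) else pos[p]

    A = np.zeros((n, n))
    parents = [(parent_pos(r.sire_id), parent_pos(r.dam_id)) for r in t.itertuples()]
    for i in range(n):
        s, d = parents[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
        for j in range(i):
            val = 0.0
            if s is not None:
                val += 0.5 * A[j, s]
            if d is not None:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return RelationshipMatrix(ids=ids, A=A)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def standardize(x) -> np.ndarray:
    """z-score with the n-1 denominator; refuses constant input."""
    arr = np.asarray(x, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise MethylAccelError("cannot standardize a constant vector")
    return (arr - arr.mean()) / sd


# ---------------------------------------------------------------------------
# Gaussian linear mixed model via REML
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    sigma2_a: float
    sigma2_e: float
    reml_loglik: float
    n: int
    converged: bool = True

    def wald_ci(self, k: int, level: float = 0.95) -> Tuple[float, float]:
        zcrit = stats.norm.ppf(0.5 + level / 2)
        return self.beta[k] - zcrit * self.se[k], self.beta[k] + zcrit * self.se[k]


_RIDGE = 1e-8


def _eigen_A(A: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    d, U = np.linalg.eigh(A)
    if d.min() < -1e-6:
        raise MethylAccelError("relationship matrix is not positive semidefinite")
    return np.maximum(d, 0.0) + _RIDGE, U


def _reml_profile(lam: float, d: np.ndarray, Xt: np.ndarray, yt: np.ndarray):
    """Profiled restricted log-likelihood at variance ratio lam = s2a/s2e."""
    n, p = Xt.shape
    w = 1.0 / (1.0 + lam * d)
    XtW = Xt * w[:, None]
    G = Xt.T @ XtW
    try:
        beta = np.linalg.solve(G, XtW.T @ yt)
    except np.linalg.LinAlgError:
        raise MethylAccelError("singular design matrix")
    r = yt - Xt @ beta
    rss = float(r @ (w * r))
    s2e = rss / (n - p)
    sign, logdetG = np.linalg.slogdet(G)
    ll = -0.5 * (np.sum(np.log(1.0 + lam * d)) + (n - p) * np.log(s2e)
                 + logdetG + (n - p))
    return ll, beta, s2e, G


def fit_gaussian_lmm(y: np.ndarray, X: np.ndarray, A: RelationshipMatrix,
                     eig: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                     fixed_ratio: Optional[float] = None) -> LMMFit:
    """REML fit of the animal model.

    ``fixed_ratio`` pins sigma_a^2/sigma_e^2 (0 reduces the model to OLS/GLS
    with independent errors); ``eig`` lets callers reuse a precomputed
    eigendecomposition of A across repeated fits.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise MethylAccelError("y and X dimensions disagree")
    if np.linalg.matrix_rank(X) < p:
        raise MethylAccelError("X is not full column rank")
    d, U = _eigen_A(A.A) if eig is None else eig
    Xt, yt = U.T @ X, U.T @ y

    if fixed_ratio is not None:
        lam = float(fixed_ratio)
        converged = True
    else:
        obj = lambda log_lam: -_reml_profile(np.exp(log_lam), d, Xt, yt)[0]
        res = optimize.minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded",
                                       options={"xatol": 1e-8})
        lam = float(np.exp(res.x))
        converged = bool(res.success)
        # boundary check: ratio ~ 0 may beat the interior optimum
        ll0 = _reml_profile(np.exp(-30.0), d, Xt, yt)[0]
        if ll0 > -res.fun:
            lam = 0.0
    ll, beta, s2e, G = _reml_profile(max(lam, 0.0) if lam > 0 else 0.0, d, Xt, yt)
    cov = s2e * np.linalg.inv(G)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LMMFit(beta=beta, se=se, p=pvals, sigma2_a=lam * s2e, sigma2_e=s2e,
                  reml_loglik=ll, n=n, converged=converged)


# ---------------------------------------------------------------------------
# Binary outcomes: probit Gibbs sampler with pedigree random effect
# ---------------------------------------------------------------------------

@dataclass
class ProbitFit:
    beta_mean: np.ndarray
    beta_ci: np.ndarray        # (p, 2) equal-tailed 95% interval
    p: np.ndarray              # two-sided MCMC tail probability per coefficient
    sigma2_a_mean: float
    n: int
    n_draws: int
    separation_warning: bool = False


def fit_binary_mixed(y: np.ndarray, X: np.ndarray, A: RelationshipMatrix,
                     iterations: int = 2000, burn_in: int = 500,
                     seed: int = 0,
                     eig: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                     fixed_sigma2_a: Optional[float] = None,
                     prior_shape: float = 0.001, prior_scale: float = 0.001) -> ProbitFit:
    """Albert-Chib latent-liability probit sampler with an additive pedigree
    random effect; residual (liability) variance fixed at 1.

    Priors: improper flat on the fixed effects; inverse-gamma(shape, scale)
    on the genetic variance. ``fixed_sigma2_a=0`` drops the random effect.
    """
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if set(np.unique(y)) - {0, 1}:
        raise MethylAccelError("binary outcome must be coded 0/1")
    if y.min() == y.max():
        raise MethylAccelError("both outcome classes must be present")
    rng = np.random.default_rng(seed)
    d, U = _eigen_A(A.A) if eig is None else eig

    XtX_inv = np.linalg.inv(X.T @ X)
    L = np.linalg.cholesky(XtX_inv)
    beta = np.zeros(p)
    a = np.zeros(n)
    sigma2_a = 0.5 if fixed_sigma2_a is None else float(fixed_sigma2_a)

    lower = np.where(y == 1, 0.0, -np.inf)
    upper = np.where(y == 1, np.inf, 0.0)

    keep = iterations - burn_in
    beta_draws = np.empty((keep, p))
    s2a_draws = np.empty(keep)
    for it in range(iterations):
        mu = X @ beta + a
        z = _truncated_normal(rng, mu, lower, upper)
        resid = z - a
        beta_hat = XtX_inv @ (X.T @ resid)
        beta = beta_hat + L @ rng.standard_normal(p)
        if sigma2_a > 0:
            # rotated random effect: a = U a_tilde, prior a_tilde ~ N(0, s2a * d)
            r = U.T @ (z - X @ beta)
            prec = 1.0 / (sigma2_a * d) + 1.0
            mean = r / prec
            a_t = mean + rng.standard_normal(n) / np.sqrt(prec)
            a = U @ a_t
            if fixed_sigma2_a is None:
                shape = prior_shape + 0.5 * n
                scale = prior_scale + 0.5 * float(np.sum(a_t**2 / d))
                sigma2_a = scale / rng.gamma(shape)
        if it >= burn_in:
            beta_draws[it - burn_in] = beta
            s2a_draws[it - burn_in] = sigma2_a

    mean = beta_draws.mean(axis=0)
    sds = beta_draws.std(axis=0)
    separation = bool(np.any(np.abs(mean) > 10) or np.any(sds > 10))
    ci = np.column_stack([np.quantile(beta_draws, 0.025, axis=0),
                          np.quantile(beta_draws, 0.975, axis=0)])
    tail = np.minimum((beta_draws > 0).mean(axis=0), (beta_draws < 0).mean(axis=0))
    pvals = np.clip(2.0 * tail, 1.0 / keep, 1.0)
    return ProbitFit(beta_mean=mean, beta_ci=ci, p=pvals,
                     sigma2_a_mean=float(s2a_draws.mean()), n=n, n_draws=keep,
                     separation_warning=separation)


def fit_gaussian_gibbs(y: np.ndarray, X: np.ndarray, A: RelationshipMatrix,
                       iterations: int = 2000, burn_in: int = 500,
                       seed: int = 0,
                       eig: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                       prior_shape: float = 0.001, prior_scale: float = 0.001) -> ProbitFit:
    """Gibbs sampler for the Gaussian animal model (fidelity mode).

    Same conditional structure as the probit sampler but with the observed
    outcome in place of the latent liability and an inverse-gamma update for
    the residual variance. Returns the same summary container.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    d, U = _eigen_A(A.A) if eig is None else eig

    XtX_inv = np.linalg.inv(X.T @ X)
    L = np.linalg.cholesky(XtX_inv)
    beta = XtX_inv @ (X.T @ y)
    a = np.zeros(n)
    sigma2_a, sigma2_e = 0.5, float(np.var(y)) or 1.0

    keep = iterations - burn_in
    beta_draws = np.empty((keep, p))
    s2a_draws = np.empty(keep)
    for it in range(iterations):
        resid = y - a
        beta_hat = XtX_inv @ (X.T @ resid)
        beta = beta_hat + np.sqrt(sigma2_e) * (L @ rng.standard_normal(p))
        r = U.T @ (y - X @ beta)
        prec = 1.0 / (sigma2_a * d) + 1.0 / sigma2_e
        mean = (r / sigma2_e) / prec
        a_t = mean + rng.standard_normal(n) / np.sqrt(prec)
        a = U @ a_t
        sigma2_a = ((prior_scale + 0.5 * float(np.sum(a_t**2 / d)))
                    / rng.gamma(prior_shape + 0.5 * n))
        e = y - X @ beta - a
        sigma2_e = ((prior_scale + 0.5 * float(e @ e))
                    / rng.gamma(prior_shape + 0.5 * n))
        if it >= burn_in:
            beta_draws[it - burn_in] = beta
            s2a_draws[it - burn_in] = sigma2_a

    mean = beta_draws.mean(axis=0)
    ci = np.column_stack([np.quantile(beta_draws, 0.025, axis=0),
                          np.quantile(beta_draws, 0.975, axis=0)])
    tail = np.minimum((beta_draws > 0).mean(axis=0), (beta_draws < 0).mean(axis=0))
    pvals = np.clip(2.0 * tail, 1.0 / keep, 1.0)
    return ProbitFit(beta_mean=mean, beta_ci=ci, p=pvals,
                     sigma2_a_mean=float(s2a_draws.mean()), n=n, n_draws=keep)


def _truncated_normal(rng, mu, lower, upper):
    """One-sided truncated normal draws via the inverse CDF."""
    a = stats.norm.cdf(lower - mu)
    b = stats.norm.cdf(upper - mu)
    u = rng.uniform(a, b)
    return mu + stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

def bonferroni_adjust(p, m: int = DEFAULT_M_TESTS,
                      alpha: float = DEFAULT_ALPHA) -> Tuple[np.ndarray, float]:
    """Adjusted p = min(1, m*p) and the significance threshold alpha/m
    (reported to 4 decimals)."""
    p = np.asarray(p, dtype=float)
    if m < 1:
        raise MethylAccelError("m must be >= 1")
    if len(p) > m:
        raise MethylAccelError(f"{len(p)} p-values exceed the stated family size m={m}")
    if np.any((p <= 0) | (p > 1)):
        raise MethylAccelError("p-values must lie in (0, 1]")
    return np.minimum(1.0, m * p), round(alpha / m, 4)


# ---------------------------------------------------------------------------
# Association suite
# ---------------------------------------------------------------------------

def run_association_suite(phenotypes: pd.DataFrame, accel: pd.DataFrame,
                          A: RelationshipMatrix,
                          exposures: Sequence[str] = ("ieaa", "eeaa"),
                          m_tests: int = DEFAULT_M_TESTS,
                          alpha: float = DEFAULT_ALPHA,
                          seed: int = 0,
                          chain: Optional[Mapping[str, int]] = None,
                          scale_education: bool = True,
                          gaussian_sampler: bool = False) -> pd.DataFrame:
    """Fit every risk factor x exposure model and return the results table.

    12 risk factors x 2 exposures = 24 rows. Continuous outcomes and the
    exposure are z-scored before fitting; binary outcomes are modelled on the
    probit liability scale. Bonferroni adjustment is applied within each
    exposure with family size ``m_tests``. ``scale_education=False`` reports
    education per ordinal unit instead of per SD. ``gaussian_sampler=True``
    routes Gaussian outcomes through the Gibbs sampler as well (fidelity
    mode); the default is the deterministic REML path.
    """
    missing = [c for c in RISK_FACTORS if c not in phenotypes.columns]
    if missing:
        raise MethylAccelError(f"phenotype table missing columns: {missing}")
    ids = accel.index
    phenos = phenotypes.loc[ids]
    Aord = A.reorder(ids)
    eig = _eigen_A(Aord.A)
    chain = dict(chain or {})
    iterations = int(chain.get("iterations", 2000))
    burn_in = int(chain.get("burn_in", 500))

    age_z = standardize(phenos["chronological_age"])
    sex01 = (phenos["sex"] == "male").astype(float).to_numpy()

    rows = []
    rng = np.random.default_rng(seed)
    for exposure in exposures:
        expo_z = standardize(accel[exposure])
        pvals = []
        for outcome, family in RISK_FACTORS.items():
            X = np.column_stack([np.ones(len(ids)), age_z, sex01, expo_z])
            k = 3  # exposure column
            if family == "gaussian":
                yvals = phenos[outcome].to_numpy(dtype=float)
                if outcome == "education" and not scale_education:
                    yz = yvals - yvals.mean()
                else:
                    yz = standardize(yvals)
                if gaussian_sampler:
                    fit = fit_gaussian_gibbs(yz, X, Aord, iterations=iterations,
                                             burn_in=burn_in,
                                             seed=int(rng.integers(2**31)), eig=eig)
                    beta = fit.beta_mean[k]
                    ci_low, ci_high = fit.beta_ci[k]
                    pval = fit.p[k]
                else:
                    fit = fit_gaussian_lmm(yz, X, Aord, eig=eig)
                    ci_low, ci_high = fit.wald_ci(k)
                    beta, pval = fit.beta[k], fit.p[k]
            else:
                y = phenos[outcome].to_numpy(dtype=int)
                fit = fit_binary_mixed(y, X, Aord, iterations=iterations,
                                       burn_in=burn_in,
                                       seed=int(rng.integers(2**31)), eig=eig)
                beta = fit.beta_mean[k]
                ci_low, ci_high = fit.beta_ci[k]
                pval = fit.p[k]
            pvals.append(pval)
            rows.append({
                "risk_factor": outcome, "family": family, "exposure": exposure,
                "beta": beta, "ci_low": ci_low, "ci_high": ci_high,
                "p": pval, "n_used": len(ids),
            })
        adj, threshold = bonferroni_adjust(pvals, m=m_tests, alpha=alpha)
        for off, padj in enumerate(adj):
            rows[len(rows) - len(adj) + off]["p_adjusted"] = padj
            rows[len(rows) - len(adj) + off]["threshold"] = threshold
    return pd.DataFrame(rows)
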