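"""Distance decay of community similarity with MLPE mixed models.

Pairwise Bray-Curtis dissimilarities are regressed on a pairwise route
distance.  Pairwise observations are not independent: two pairs sharing a
site are correlated.  The maximum-likelihood-population-effects (MLPE)
model handles this with the covariance

    cov(eps_ij, eps_kl) = sigma^2 * [ 1 if (ij)=(kl); rho if the pairs
                                      share exactly one site; 0 otherwise ]

with rho in [0, 0.5) (positive definiteness).  Writing Z for the pairs-by-
sites incidence matrix (two ones per row), the correlation matrix is
C(rho) = (1-2 rho) I + rho Z Z'.  Since Z Z' is fixed, one eigen-
decomposition makes every likelihood evaluation O(N) in the number of
pairs, and the full ML fit reduces to a 1-D optimization over rho.

The effect size of the distance term is Rbeta^2 = qF / (qF + nu), with F
the fixed-effect Wald F, q its numerator df, and nu a Satterthwaite-style
approximation of the denominator df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit, logit

from .geometry import DistanceTriplet

__all__ = ["MLPEFit", "bray_curtis", "fit_mlpe", "r2_beta", "compare_routes"]


def bray_curtis(raw) -> pd.DataFrame:
    """Site-by-site Bray-Curtis dissimilarity from abundances.

    BC_ij = sum_k |y_ik - y_jk| / sum_k (y_ik + y_jk).  Sites with zero
    total abundance are rejected (the value would be undefined).
    """
    ab = raw.abundance if hasattr(raw, "abundance") else raw
    a = ab.to_numpy(float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = list(ab.index[a.sum(axis=1) == 0])
    if zero:
        raise ValueError(f"sites with zero total abundance: {zero}")
    d = squareform(pdist(a, metric="braycurtis"))
    return pd.DataFrame(d, index=ab.index, columns=ab.index)


@dataclass
class MLPEFit:
    """Maximum-likelihood MLPE fit of dissimilarity on one distance."""

    beta0: float              # intercept
    beta1: float              # slope per km of distance
    rho: float                # shared-site correlation, in [0, 0.5)
    sigma2: float             # residual variance
    loglik: float
    F: float                  # Wald F for the distance term
    q: int                    # numerator df (1)
    nu: float                 # Satterthwaite-style denominator df
    n_pairs: int
    n_sites: int
    converged: bool
    se_beta1: float
    df_method: str = "satterthwaite"

    @property
    def r2_beta(self) -> float:
        return r2_beta(self)


def _pairs_from_matrices(D: pd.DataFrame, X: pd.DataFrame):
    """Extract upper-triangle pairs common to both matrices; drop pairs with
    a missing distance."""
    sites = list(D.index)
    X = X.loc[sites, sites]
    d = D.to_numpy(float)
    x = X.to_numpy(float)
    iu, ju = np.triu_indices(len(sites), k=1)
    keep = np.isfinite(x[iu, ju]) & np.isfinite(d[iu, ju])
    return d[iu, ju][keep], x[iu, ju][keep], iu[keep], ju[keep], len(sites)


class _MLPEKernel:
    """Precomputed eigenstructure of Z Z' for fast profile-likelihood."""

    def __init__(self, y, x, iu, ju, n_sites):
        N = y.size
        z = np.zeros((N, n_sites))
        z[np.arange(N), iu] = 1.0
        z[np.arange(N), ju] = 1.0
        gamma, Q = np.linalg.eigh(z @ z.T)
        self.gamma = gamma
        self.yt = Q.T @ y
        self.Xt = Q.T @ np.column_stack([np.ones(N), x])
        self.N = N

    def eigvals(self, rho):
        return (1.0 - 2.0 * rho) + rho * self.gamma

    def profile(self, rho):
        """GLS beta, profiled sigma^2, and the ML log-likelihood at rho."""
        lam = self.eigvals(rho)
        w = 1.0 / lam
        Xw = self.Xt * w[:, None]
        xtx = self.Xt.T @ Xw
        xty = Xw.T @ self.yt
        beta = np.linalg.solve(xtx, xty)
        resid = self.yt - self.Xt @ beta
        rss = float(np.sum(resid * resid * w))
        sigma2 = rss / self.N
        ll = -0.5 * (self.N * np.log(2 * np.pi * max(sigma2, 1e-300))
                     + np.sum(np.log(lam)) + self.N)
        return beta, sigma2, ll, xtx

    def loglik(self, rho, sigma2, beta):
        lam = sigma2 * self.eigvals(rho)
        resid = self.yt - self.Xt @ beta
        return float(-0.5 * (self.N * np.log(2 * np.pi)
                             + np.sum(np.log(lam))
                             + np.sum(resid * resid / lam)))

    def gls(self, rho):
        """GLS estimate of beta with the correlation fixed at rho."""
        beta, sigma2, _, xtx = self.profile(rho)
        cov = sigma2 * np.linalg.inv(xtx)
        return beta, cov


_RHO_MAX = 0.5 - 1e-6


def _wald_f(beta, sigma2, xtx, y):
    """Wald F for the slope; 0 for a numerically perfect (flat) fit."""
    scale = max(float(np.var(y)), float(np.mean(y * y)), 1e-300)
    if sigma2 <= 1e-20 * scale:
        return 0.0, 0.0
    cov_beta = sigma2 * np.linalg.inv(xtx)
    se1 = float(np.sqrt(max(cov_beta[1, 1], 0.0)))
    if se1 == 0.0:
        return np.inf, 0.0
    return float((beta[1] / se1) ** 2), se1


def fit_mlpe(
    D: pd.DataFrame,
    X: pd.DataFrame,
    drop_pairs=None,
    seed: int | None = None,
    fix_rho: float | None = None,
) -> MLPEFit:
    """Fit the MLPE model BC_ij = beta0 + beta1 * d_ij + eps by ML.

    ``drop_pairs`` is an optional iterable of (site_a, site_b) tuples to
    exclude.  Pairs with a missing distance are dropped automatically.
    Optimization runs from three fixed starting values of rho with a
    seedable jitter on restart; non-convergence raises with diagnostics.
    ``fix_rho`` holds the shared-site correlation at a known value and
    estimates beta by generalized least squares (no optimization).
    """
    D = D.copy()
    if drop_pairs:
        for a, b in drop_pairs:
            D.loc[a, b] = np.nan
            D.loc[b, a] = np.nan
        X = X  # distance matrix untouched; the pair is removed below
        for a, b in drop_pairs:
            X = X.copy()
            X.loc[a, b] = np.nan
            X.loc[b, a] = np.nan
    y, x, iu, ju, n_sites = _pairs_from_matrices(D, X)
    if n_sites < 6:
        raise ValueError("MLPE needs at least 6 sites")
    if y.size < 4:
        raise ValueError("too few complete pairs to fit")
    kern = _MLPEKernel(y, x, iu, ju, n_sites)

    if fix_rho is not None:
        if not 0.0 <= fix_rho < 0.5:
            raise ValueError("fix_rho must lie in [0, 0.5)")
        beta, sigma2, ll, xtx = kern.profile(fix_rho)
        F, se1 = _wald_f(beta, sigma2, xtx, y)
        nu = _satterthwaite_nu(kern, fix_rho, sigma2, beta)
        return MLPEFit(
            beta0=float(beta[0]), beta1=float(beta[1]), rho=float(fix_rho),
            sigma2=float(sigma2), loglik=float(ll), F=F, q=1, nu=nu,
            n_pairs=int(y.size), n_sites=n_sites, converged=True, se_beta1=se1,
        )

    def neg_ll(theta):
        rho = _RHO_MAX * expit(theta)
        return -kern.profile(rho)[2]

    rng = np.random.default_rng(seed)
    best = None
    starts = [logit(0.02 / _RHO_MAX), logit(0.2 / _RHO_MAX), logit(0.4 / _RHO_MAX)]
    for attempt, t0 in enumerate(starts):
        t0 = t0 + (rng.normal(0, 0.1) if attempt else 0.0)
        res = minimize_scalar(neg_ll, bounds=(t0 - 8.0, t0 + 8.0), method="bounded",
                              options={"maxiter": 500, "xatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("MLPE optimization failed to converge after restarts")
    rho = float(_RHO_MAX * expit(best.x))
    beta, sigma2, ll, xtx = kern.profile(rho)
    F, se1 = _wald_f(beta, sigma2, xtx, y)
    nu = _satterthwaite_nu(kern, rho, sigma2, beta)
    return MLPEFit(
        beta0=float(beta[0]), beta1=float(beta[1]), rho=rho, sigma2=float(sigma2),
        loglik=float(ll), F=F, q=1, nu=nu, n_pairs=int(y.size), n_sites=n_sites,
        converged=bool(np.isfinite(best.fun)), se_beta1=se1,
    )


def _satterthwaite_nu(kern: _MLPEKernel, rho: float, sigma2: float, beta) -> float:
    """Satterthwaite-style denominator df for the slope contrast.

    nu = 2 c^2 / Var(c) with c = var(beta1_hat) as a function of the
    variance parameters theta = (sigma2, rho); Var(c) = g' V g with g the
    numerical gradient of c and V the inverse observed information of the
    ML log-likelihood in theta (beta held at its estimate).
    """

    def c_of(theta):
        s2, r = theta
        r = float(np.clip(r, 0.0, _RHO_MAX))
        lam = kern.eigvals(r)
        Xw = kern.Xt / lam[:, None]
        xtx = kern.Xt.T @ Xw
        return s2 * np.linalg.inv(xtx)[1, 1]

    def ll_of(theta):
        s2, r = theta
        if s2 <= 0 or not (0.0 <= r < 0.5):
            return -np.inf
        return kern.loglik(r, s2, beta)

    theta = np.array([sigma2, rho])
    h = np.array([max(1e-6, 1e-4 * sigma2), 1e-4])
    # numerical Hessian of the log-likelihood (observed information)
    H = np.zeros((2, 2))
    for a in range(2):
        for b in range(2):
            ta = np.array(theta)
            pts = []
            for sa in (1, -1):
                for sb in (1, -1):
                    t = np.array(theta)
                    t[a] += sa * h[a]
                    t[b] += sb * h[b]
                    pts.append(sa * sb * ll_of(t))
            H[a, b] = sum(pts) / (4 * h[a] * h[b])
            _ = ta
    info = -H
    try:
        V = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float(kern.N - 2)
    g = np.zeros(2)
    for a in range(2):
        t1, t2 = np.array(theta), np.array(theta)
        t1[a] += h[a]
        t2[a] -= h[a]
        t2[a] = max(t2[a], 1e-12) if a == 0 else max(t2[a], 0.0)
        g[a] = (c_of(t1) - c_of(t2)) / (t1[a] - t2[a])
    c = c_of(theta)
    var_c = float(g @ V @ g)
    if var_c <= 0 or not np.isfinite(var_c):
        return float(kern.N - 2)
    nu = 2.0 * c * c / var_c
    return float(np.clip(nu, 1.0, 10.0 * kern.N))


def r2_beta(fit: MLPEFit) -> float:
    """Effect size Rbeta^2 = qF / (qF + nu) of the fixed distance effect."""
    if fit.nu <= 0:
        raise ValueError("denominator df must be positive")
    if not np.isfinite(fit.F):
        return 1.0
    qF = fit.q * fit.F
    return float(qF / (qF + fit.nu))


def compare_routes(D: pd.DataFrame, triplet: DistanceTriplet, seed: int | None = None) -> pd.DataFrame:
    """Fit one MLPE per route (GEO/TOP/WAT) and tabulate Rbeta^2.

    Each route uses its own complete pairs (missing watercourse pairs are
    dropped and counted).  Routes with no complete pair are skipped; if all
    are unusable an error is raised.  The returned table is sorted by the
    original route order and carries a ``rank`` column by descending
    Rbeta^2.
    """
    rows = []
    for name, X in triplet.items():
        x = X.to_numpy(float)
        iu = np.triu_indices(len(X), k=1)
        n_missing = int(np.isnan(x[iu]).sum())
        if np.isnan(x[iu]).all():
            continue
        fit = fit_mlpe(D, X, seed=seed)
        rows.append({
            "route": name, "beta0": fit.beta0, "beta1": fit.beta1, "rho": fit.rho,
            "F": fit.F, "q": fit.q, "nu": fit.nu, "r2_beta": fit.r2_beta,
            "n_pairs": fit.n_pairs, "n_missing_pairs": n_missing,
        })
    if not rows:
        raise ValueError("no route has any complete site pair")
    table = pd.DataFrame(rows).set_index("route")
    table["rank"] = table["r2_beta"].rank(ascending=False).astype(int)
    return table
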