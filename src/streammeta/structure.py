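"""Multivariate dispersion (PERMDISP) and null-model diversity partitioning.

PERMDISP compares the spread of groups of sites in the space of a
dissimilarity matrix: sites are embedded by principal coordinates (keeping
negative-eigenvalue axes), each site's distance to its group centroid is
corrected as sqrt(max(0, d_real^2 - d_imag^2)), a one-way ANOVA F compares
groups, and significance comes from permuting group labels (group sizes
fixed) with centroids recomputed each time.

Additive diversity partitioning splits richness-based gamma diversity into
the mean within-site alpha and the among-site beta = gamma - mean(alpha).
Whether the observed beta exceeds chance is judged against null community
matrices with both row (site) and column (taxon) totals fixed, drawn by the
Patefield algorithm; the standardized effect size is
SES = (obs - mean_null) / sd_null.  In this two-level partition
alpha + beta = gamma exactly, so SES(alpha) = -SES(beta).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.stats import random_table

__all__ = [
    "DispersionResult",
    "DiversityPartition",
    "permdisp",
    "env_heterogeneity",
    "additive_partition",
    "null_matrices_r2table",
    "diversity_ses",
]


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------


@dataclass
class DispersionResult:
    """PERMDISP outcome: per-group dispersions, F and permutation p."""

    group_means: pd.DataFrame  # mean distance-to-centroid and SE per group
    F: float
    p: float
    n_perm: int
    distances: pd.Series       # per-site distance to its group centroid


def _pcoa_coords(D: np.ndarray):
    """Principal-coordinate embedding, split into real and imaginary parts.

    Gower-center -D^2/2 and eigendecompose; axes with positive eigenvalues
    give real coordinates scaled by sqrt(lambda), negative eigenvalues give
    'imaginary' coordinates scaled by sqrt(-lambda).
    """
    n = D.shape[0]
    a = -0.5 * D**2
    h = np.eye(n) - np.ones((n, n)) / n
    g = h @ a @ h
    lam, v = np.linalg.eigh((g + g.T) / 2)
    tol = 1e-9 * max(1.0, np.abs(lam).max())
    pos = lam > tol
    neg = lam < -tol
    real = v[:, pos] * np.sqrt(lam[pos])
    imag = v[:, neg] * np.sqrt(-lam[neg])
    return real, imag


def _dist_to_centroids(real, imag, codes, n_groups):
    """Corrected distance of each site to its group centroid."""
    d2 = np.zeros(real.shape[0])
    for g in range(n_groups):
        idx = codes == g
        cr = real[idx].mean(axis=0)
        dr2 = np.sum((real[idx] - cr) ** 2, axis=1)
        if imag.shape[1]:
            ci = imag[idx].mean(axis=0)
            di2 = np.sum((imag[idx] - ci) ** 2, axis=1)
        else:
            di2 = 0.0
        d2[idx] = np.maximum(0.0, dr2 - di2)
    return np.sqrt(d2)


def _anova_f(values, codes, n_groups):
    n = values.size
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        m = v.mean()
        ss_between += v.size * (m - grand) ** 2
        ss_within += float(np.sum((v - m) ** 2))
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within <= 0:
        return 0.0 if ss_between <= 0 else np.inf
    return (ss_between / df_b) / (ss_within / df_w)


def permdisp(D: pd.DataFrame, groups, n_perm: int = 1000, seed: int | None = None) -> DispersionResult:
    """Test homogeneity of multivariate dispersions among groups.

    ``groups`` maps each site (in the order of ``D``) to a group label; every
    group needs at least 2 sites.  The permutation p-value uses the
    (b+1)/(m+1) estimator over ``n_perm`` random relabelings.
    """
    groups = pd.Series(np.asarray(groups), index=D.index)
    labels, codes = np.unique(groups.to_numpy(), return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = labels[sizes < 2].tolist()
        raise ValueError(f"groups with fewer than 2 sites: {small}")
    a = D.to_numpy(float)
    real, imag = _pcoa_coords(a)
    dist = _dist_to_centroids(real, imag, codes, labels.size)
    F = _anova_f(dist, codes, labels.size)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        dstar = _dist_to_centroids(real, imag, perm, labels.size)
        if _anova_f(dstar, perm, labels.size) >= F - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    rows = []
    for g, lab in enumerate(labels):
        v = dist[codes == g]
        se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        rows.append({"group": lab, "mean_dist": float(v.mean()), "se": se, "n": int(v.size)})
    return DispersionResult(
        group_means=pd.DataFrame(rows).set_index("group"),
        F=float(F), p=float(p), n_perm=n_perm,
        distances=pd.Series(dist, index=D.index, name="dist_to_centroid"),
    )


def env_heterogeneity(env: pd.DataFrame, groups, n_perm: int = 1000, seed: int | None = None) -> DispersionResult:
    """PERMDISP preset on Euclidean distances of z-standardized environment."""
    a = env.to_numpy(float)
    sd = a.std(axis=0, ddof=1)
    z = (a - a.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    diff = z[:, None, :] - z[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2))
    D = pd.DataFrame(d, index=env.index, columns=env.index)
    return permdisp(D, groups, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# diversity partitioning
# ---------------------------------------------------------------------------


def additive_partition(raw) -> tuple[float, float, float]:
    """Richness-based additive partition: (gamma, mean alpha, beta).

    alpha_i is the number of taxa present at site i, gamma the number of
    taxa present anywhere, and beta = gamma - mean(alpha) >= 0.
    """
    ab = raw.abundance if hasattr(raw, "abundance") else raw
    a = ab.to_numpy(float)
    if a.size == 0 or a.shape[0] < 2:
        raise ValueError("need a non-empty matrix with at least 2 sites")
    pres = a > 0
    alpha = pres.sum(axis=1).mean()
    gamma = float((pres.any(axis=0)).sum())
    return gamma, float(alpha), float(gamma - alpha)


def null_matrices_r2table(raw, n_null: int, seed: int | None = None) -> Iterator[np.ndarray]:
    """Stream of fixed-row, fixed-column null matrices (Patefield algorithm).

    Each draw is uniform over individual-level reallocations preserving both
    margins; margins of every draw are verified exactly before it is
    yielded.  Non-integer abundances are rejected.
    """
    ab = raw.abundance if hasattr(raw, "abundance") else raw
    a = np.asarray(ab, float) if not isinstance(ab, pd.DataFrame) else ab.to_numpy(float)
    if not np.allclose(a, np.round(a)):
        raise ValueError(
            "r2table requires integer abundances; round your data explicitly first")
    a = np.round(a).astype(np.int64)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    rows = a.sum(axis=1)
    cols = a.sum(axis=0)
    rng = np.random.default_rng(seed)
    if a.shape[0] == 1 or a.shape[1] == 1:
        # a single row or column is fully determined by its margins
        for _ in range(n_null):
            yield a.copy()
        return
    dist = random_table(rows, cols)
    for _ in range(n_null):
        m = dist.rvs(method="patefield", random_state=rng)
        m = np.asarray(m, np.int64)
        assert (m.sum(axis=1) == rows).all() and (m.sum(axis=0) == cols).all(), \
            "null matrix margins do not match the original"
        yield m


@dataclass
class DiversityPartition:
    """Observed partition with its fixed-margins null distribution."""

    gamma: float
    alpha: float
    beta: float
    null_beta: np.ndarray
    ses_beta: float | None
    ses_alpha: float | None
    p: float | None
    n_null: int

    def summary(self) -> dict:
        return {
            "gamma": self.gamma, "alpha": self.alpha, "beta": self.beta,
            "ses_beta": self.ses_beta, "ses_alpha": self.ses_alpha,
            "p": self.p, "n_null": self.n_null,
        }


def diversity_ses(raw, n_null: int = 999, seed: int | None = None) -> DiversityPartition:
    """SES of the beta (and alpha) partition against the r2table null.

    SES = (observed - null mean) / null sd; the two-sided p-value is the
    rank of the observed beta in the null distribution.  If the null sd is
    zero the SES is reported as None ('undefined').
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    gamma, alpha, beta = additive_partition(raw)
    null_beta = np.array([
        gamma_a[2] for gamma_a in (
            additive_partition(pd.DataFrame(m)) for m in null_matrices_r2table(raw, n_null, seed))
    ])
    sd = float(null_beta.std(ddof=1))
    if sd == 0:
        ses_b = ses_a = None
        p = None
    else:
        ses_b = float((beta - null_beta.mean()) / sd)
        ses_a = -ses_b  # alpha + beta = gamma with gamma fixed by the margins
        hi = int(np.sum(null_beta >= beta - 1e-12))
        lo = int(np.sum(null_beta <= beta + 1e-12))
        p = min(1.0, 2.0 * (min(hi, lo) + 1) / (n_null + 1))
    return DiversityPartition(gamma, alpha, beta, null_beta, ses_b, ses_a, p, n_null)
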