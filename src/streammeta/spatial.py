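"""Spatial weighting matrices, Moran's eigenvector maps and spectral surrogates.

A spatial weighting matrix (SWM) combines a connectivity graph over the
sites (Gabriel graph, relative-neighbourhood graph, minimum spanning tree
or a distance band) with an edge-weighting function (binary, linear decay,
or concave-down 1/d^alpha).  Moran's eigenvector maps (MEM) are the
eigenvectors of the doubly-centered SWM restricted to the orthocomplement
of the constant vector; sorted by descending eigenvalue they provide
orthogonal spatial predictors ordered from broad positive autocorrelation
to fine-scale negative autocorrelation.  Moran's I of eigenvector k is the
exact identity I_k = (n / sum(W)) * lambda_k.

Moran spectral randomization (MSR) builds surrogate variables that keep a
variable's spatial autocorrelation spectrum: the variable is expressed in
the full MEM basis and the coefficients' signs are flipped at random, the
same sign vector being applied to every column so that cross-correlations
are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform

__all__ = [
    "SpatialWeightingMatrix",
    "MEMBasis",
    "MSRSurrogates",
    "SelectionResult",
    "build_swm",
    "candidate_swms",
    "compute_mem",
    "select_swm",
    "forward_select",
    "msr_surrogates",
    "morans_i",
]

GRAPH_KINDS = ("gabriel", "relative_neighborhood", "mst", "distance_band")
WEIGHT_KINDS = ("binary", "linear_decay", "concave_down")


@dataclass
class SpatialWeightingMatrix:
    """Symmetric non-negative weights on a site connectivity graph."""

    weights: pd.DataFrame
    graph_kind: str
    weight_kind: str
    source: str = "GEO"
    connected: bool = True
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.weights)

    def label(self) -> str:
        extra = "".join(f",{k}={v:g}" for k, v in self.params.items())
        return f"{self.graph_kind}/{self.weight_kind}{extra}"


@dataclass
class MEMBasis:
    """Moran eigenvectors (columns of U, unit norm, orthogonal to constants)."""

    vectors: pd.DataFrame      # sites x (n-1), sorted by descending eigenvalue
    eigenvalues: np.ndarray
    morans_i: np.ndarray
    swm: SpatialWeightingMatrix

    @property
    def positive(self) -> pd.DataFrame:
        """The positive-eigenvalue (positively autocorrelated) MEMs."""
        return self.vectors.loc[:, self.eigenvalues > 1e-10]

    @property
    def n_positive(self) -> int:
        return int((self.eigenvalues > 1e-10).sum())


@dataclass
class MSRSurrogates:
    """Spectrum-preserving surrogate datasets (one array per replicate)."""

    replicates: list[pd.DataFrame]
    method: str
    seed: int | None

    def __len__(self) -> int:
        return len(self.replicates)

    def __iter__(self):
        return iter(self.replicates)


@dataclass
class SelectionResult:
    """Outcome of forward selection with the double stopping rule."""

    selected: list            # column labels in selection order
    step_p: list[float]
    cumulative_adj_r2: list[float]
    global_p: float
    global_adj_r2: float
    stopped_by: str           # 'global', 'alpha', 'adjr2', 'exhausted'

    @property
    def significant(self) -> bool:
        return len(self.selected) > 0

    def truncate(self, k: int) -> list:
        """The first ``k`` variables in selection order (the retained set)."""
        return self.selected[:k]


# ---------------------------------------------------------------------------
# graphs and weights
# ---------------------------------------------------------------------------


def _gabriel_edges(d2: np.ndarray) -> np.ndarray:
    """Adjacency of the Gabriel graph from squared distances.

    Edge (i, j) is kept iff no third point k lies inside the closed disc
    with diameter ij, i.e. d2[i,k] + d2[j,k] > d2[i,j] for all k.
    """
    n = d2.shape[0]
    adj = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(i + 1, n):
            s = d2[i] + d2[j]
            mask = np.ones(n, bool)
            mask[[i, j]] = False
            if np.all(s[mask] > d2[i, j] + 1e-12):
                adj[i, j] = adj[j, i] = True
    return adj


def _rng_edges(d: np.ndarray) -> np.ndarray:
    """Relative-neighbourhood graph: keep (i,j) iff no k with
    max(d_ik, d_jk) < d_ij."""
    n = d.shape[0]
    adj = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(i + 1, n):
            m = np.maximum(d[i], d[j])
            mask = np.ones(n, bool)
            mask[[i, j]] = False
            if np.all(m[mask] >= d[i, j] - 1e-12):
                adj[i, j] = adj[j, i] = True
    return adj


def _mst_edges(d: np.ndarray) -> np.ndarray:
    t = minimum_spanning_tree(d).toarray()
    return (t + t.T) > 0


def _is_connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    seen = np.zeros(n, bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return bool(seen.all())


def build_swm(
    d: pd.DataFrame,
    graph_kind: str = "gabriel",
    weight_kind: str = "binary",
    *,
    band_quantile: float = 0.25,
    alpha: float = 1.0,
    source: str = "GEO",
) -> SpatialWeightingMatrix:
    """Build a spatial weighting matrix from a complete distance matrix.

    ``distance_band`` connects all pairs closer than the ``band_quantile``
    quantile of off-diagonal distances (at least the minimum that keeps the
    graph connected is *not* enforced; a disconnected graph is flagged).
    Weights: binary 1; ``linear_decay`` 1 - d/max(d); ``concave_down``
    1/d^alpha.
    """
    if graph_kind not in GRAPH_KINDS:
        raise ValueError(f"graph_kind must be one of {GRAPH_KINDS}")
    if weight_kind not in WEIGHT_KINDS:
        raise ValueError(f"weight_kind must be one of {WEIGHT_KINDS}")
    a = d.to_numpy(float)
    if np.isnan(a).any():
        raise ValueError("SWM construction needs a complete distance matrix")
    n = a.shape[0]
    params: dict = {}
    if graph_kind == "gabriel":
        adj = _gabriel_edges(a**2)
    elif graph_kind == "relative_neighborhood":
        adj = _rng_edges(a)
    elif graph_kind == "mst":
        adj = _mst_edges(a)
    else:
        thr = float(np.quantile(squareform(a, checks=False), band_quantile))
        adj = (a <= thr) & ~np.eye(n, dtype=bool)
        params["band_quantile"] = band_quantile

    w = adj.astype(float)
    if weight_kind == "linear_decay":
        dmax = a[adj].max() if adj.any() else 1.0
        w = np.where(adj, 1.0 - a / dmax, 0.0)
        # keep the longest edge connected with a tiny positive weight
        w[adj & (w <= 0)] = 1e-6
    elif weight_kind == "concave_down":
        with np.errstate(divide="ignore"):
            w = np.where(adj, 1.0 / np.maximum(a, 1e-12) ** alpha, 0.0)
        params["alpha"] = alpha
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return SpatialWeightingMatrix(
        weights=pd.DataFrame(w, index=d.index, columns=d.columns),
        graph_kind=graph_kind,
        weight_kind=weight_kind,
        source=source,
        connected=_is_connected(adj),
        params=params,
    )


def candidate_swms(
    d: pd.DataFrame,
    graph_kinds=("gabriel", "relative_neighborhood", "mst", "distance_band"),
    weight_kinds=("binary", "linear_decay"),
    band_quantiles=(0.2, 0.35, 0.5),
    source: str = "GEO",
) -> list[SpatialWeightingMatrix]:
    """The default candidate SWM grid (distance bands at three quantiles)."""
    out = []
    for g in graph_kinds:
        qs = band_quantiles if g == "distance_band" else (None,)
        for q in qs:
            for wk in weight_kinds:
                kw = {"band_quantile": q} if q is not None else {}
                out.append(build_swm(d, g, wk, source=source, **kw))
    return out


# ---------------------------------------------------------------------------
# Moran eigenvectors
# ---------------------------------------------------------------------------


def compute_mem(swm: SpatialWeightingMatrix) -> MEMBasis:
    """Eigendecompose the doubly-centered SWM into Moran eigenvector maps.

    The decomposition is carried out in an orthonormal basis of the
    orthocomplement of the constant vector, which removes the constant
    direction exactly (no reliance on an eigenvalue tolerance).
    """
    w = swm.weights.to_numpy(float)
    if not np.allclose(w, w.T):
        raise ValueError("SWM must be symmetric")
    n = w.shape[0]
    # orthonormal basis of 1^perp via QR of [1 | I]
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), np.eye(n)[:, : n - 1]]))
    qc = q[:, 1:]                      # n x (n-1), columns orthogonal to 1
    b = qc.T @ w @ qc
    lam, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    u = qc @ v[:, order]
    # sign convention: first nonzero loading positive
    for k in range(u.shape[1]):
        col = u[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            u[:, k] = -col
    cols = [f"MEM{k + 1}" for k in range(u.shape[1])]
    vectors = pd.DataFrame(u, index=swm.weights.index, columns=cols)
    moran = (n / w.sum()) * lam
    return MEMBasis(vectors=vectors, eigenvalues=lam, morans_i=moran, swm=swm)


def morans_i(x: np.ndarray, w: np.ndarray) -> float:
    """Moran's I of a variable against a symmetric weight matrix."""
    x = np.asarray(x, float)
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        return 0.0
    n = x.size
    return float(n / w.sum() * (z @ w @ z) / denom)


# ---------------------------------------------------------------------------
# R^2 helpers (shared with variation partitioning)
# ---------------------------------------------------------------------------


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _r2(yc: np.ndarray, x: np.ndarray, ss_tot: float) -> float:
    """Unadjusted redundancy-analysis R^2 of centered Y on predictors X."""
    xc = _center(np.asarray(x, float))
    if xc.size == 0:
        return 0.0
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fit = xc @ coef
    return float(np.sum(fit * fit) / ss_tot)


def _adj(r2: float, n: int, p: int) -> float:
    if p == 0:
        return r2
    if n - p - 1 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------


def forward_select(
    Y,
    X,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> SelectionResult:
    """Forward selection of predictor columns with the double stopping rule.

    First a global permutation test of Y on all columns of X; if it is not
    significant at ``alpha`` no variable is selected.  Otherwise columns are
    added greedily by added R^2; a column is admitted only while its partial
    permutation p-value is <= ``alpha`` and the model built so far has not
    yet reached the adjusted R^2 of the global model (the ceiling is checked
    before each admission round: because Ezekiel's adjustment is unbiased,
    a model already containing all real predictors sits at the global
    adjusted R^2 in expectation, and a check after admission would reject a
    true variable on a coin flip).  Permutation p-values use the
    (b+1)/(m+1) estimator.  Ties in added R^2 (within 1e-12) break by
    column order; constant columns are excluded.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    labels = list(Xf.columns)
    xa = Xf.to_numpy(float)
    if not np.isfinite(xa).all():
        raise ValueError("predictor columns must be finite")
    keep = [k for k in range(xa.shape[1]) if np.ptp(xa[:, k]) > 0]
    labels = [labels[k] for k in keep]
    xa = xa[:, keep]
    ya = Y.to_numpy(float) if isinstance(Y, (pd.DataFrame, pd.Series)) else np.asarray(Y, float)
    if ya.ndim == 1:
        ya = ya[:, None]
    n = ya.shape[0]
    yc = _center(ya)
    ss_tot = float(np.sum(yc * yc))
    if ss_tot == 0:
        raise ValueError("response has zero variance")

    # global test: permute rows of Y
    r2_global = _r2(yc, xa, ss_tot)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _r2(yc[perm], xa, ss_tot) >= r2_global:
            exceed += 1
    global_p = (exceed + 1) / (n_perm + 1)
    adj_global = _adj(r2_global, n, xa.shape[1])
    if global_p > alpha:
        return SelectionResult([], [], [], global_p, adj_global, "global")

    selected: list[int] = []
    step_p: list[float] = []
    cum_adj: list[float] = []
    r2_cur = 0.0
    stopped = "exhausted"
    while len(selected) < xa.shape[1]:
        if selected and cum_adj[-1] >= adj_global - 1e-12:
            stopped = "adjr2"
            break
        remaining = [k for k in range(xa.shape[1]) if k not in selected]
        best_k, best_add = None, -np.inf
        for k in remaining:
            cand = xa[:, selected + [k]]
            add = _r2(yc, cand, ss_tot) - r2_cur
            if add > best_add + 1e-12:
                best_add, best_k = add, k
        # partial permutation test: permute residuals of Y on current set
        if selected:
            xs = _center(xa[:, selected])
            coef, *_ = np.linalg.lstsq(xs, yc, rcond=None)
            fit = xs @ coef
        else:
            fit = np.zeros_like(yc)
        resid = yc - fit
        cols = xa[:, selected + [best_k]]
        exceed = 0
        for _ in range(n_perm):
            ystar = fit + resid[rng.permutation(n)]
            ystar = _center(ystar)
            sstar = float(np.sum(ystar * ystar))
            add_star = _r2(ystar, cols, sstar) - _r2(ystar, xa[:, selected], sstar)
            if add_star >= best_add:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
        if p > alpha:
            stopped = "alpha"
            break
        new_adj = _adj(r2_cur + best_add, n, len(selected) + 1)
        selected.append(best_k)
        step_p.append(p)
        cum_adj.append(new_adj)
        r2_cur += best_add
    return SelectionResult(
        [labels[k] for k in selected], step_p, cum_adj, global_p, adj_global, stopped
    )


# ---------------------------------------------------------------------------
# SWM selection
# ---------------------------------------------------------------------------


def select_swm(
    Y,
    candidates: list[SpatialWeightingMatrix],
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int | None = None,
) -> tuple[SpatialWeightingMatrix | None, pd.DataFrame]:
    """Pick the best SWM by corrected AIC of Y on its forward-selected
    positive MEMs.

    Each candidate's positive MEMs are forward-selected against Y and the
    candidate is scored by AICc computed from the residual sum of squares of
    Y on the selected vectors (parameters = selected + 1).  Candidates whose
    global test fails are unscored; if none passes, ``(None, report)`` is
    returned.  Ties break by candidate order.
    """
    if not candidates:
        raise ValueError("need at least one candidate SWM")
    ya = Y.to_numpy(float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    yc = _center(ya)
    n = yc.shape[0]
    ss_tot = float(np.sum(yc * yc))
    rows = []
    best_idx, best_aicc = None, np.inf
    for idx, cand in enumerate(candidates):
        basis = compute_mem(cand)
        pos = basis.positive
        if pos.shape[1] == 0:
            rows.append({"candidate": cand.label(), "n_selected": 0, "aicc": np.nan,
                         "global_p": np.nan, "note": "no positive MEMs"})
            continue
        sel = forward_select(yc, pos, alpha=alpha, n_perm=n_perm, seed=seed)
        if not sel.significant:
            rows.append({"candidate": cand.label(), "n_selected": 0, "aicc": np.nan,
                         "global_p": sel.global_p, "note": "global test n.s."})
            continue
        xs = _center(pos.loc[:, sel.selected].to_numpy(float))
        coef, *_ = np.linalg.lstsq(xs, yc, rcond=None)
        rss = float(np.sum((yc - xs @ coef) ** 2))
        k = len(sel.selected) + 1
        aicc = n * np.log(max(rss, 1e-300) / n) + 2 * k
        if n - k - 1 > 0:
            aicc += 2 * k * (k + 1) / (n - k - 1)
        rows.append({"candidate": cand.label(), "n_selected": len(sel.selected),
                     "aicc": aicc, "global_p": sel.global_p, "note": ""})
        if aicc < best_aicc - 1e-12:
            best_aicc, best_idx = aicc, idx
    report = pd.DataFrame(rows)
    _ = ss_tot
    if best_idx is None:
        return None, report
    return candidates[best_idx], report


# ---------------------------------------------------------------------------
# Moran spectral randomization
# ---------------------------------------------------------------------------


def msr_surrogates(
    X,
    basis: MEMBasis,
    T: int,
    seed: int | None = None,
) -> MSRSurrogates:
    """Sign-flip MSR surrogates of the columns of X.

    Each column is expressed in the full (n-1)-vector MEM basis; surrogate
    coefficients are the originals with independent random signs per
    eigenvector, the same sign vector applied to every column (preserving
    cross-correlations).  Surrogates are rescaled to the original column
    means and variances; the squared Moran spectrum, and hence Moran's I,
    is preserved exactly.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    if list(Xf.index) != list(basis.vectors.index):
        if len(Xf) != len(basis.vectors):
            raise ValueError("X and MEM basis cover different site sets")
    rng = np.random.default_rng(seed)
    xa = Xf.to_numpy(float)
    mu = xa.mean(axis=0)
    sd = xa.std(axis=0, ddof=0)
    u = basis.vectors.to_numpy(float)          # n x (n-1), orthonormal
    r = u.T @ (xa - mu)                        # coefficients per column
    reps = []
    for _ in range(T):
        s = rng.choice([-1.0, 1.0], size=r.shape[0])
        xs = u @ (r * s[:, None])
        # rescale to original mean / variance (exact up to roundoff already)
        cur_sd = xs.std(axis=0, ddof=0)
        scale = np.where(cur_sd > 0, sd / np.where(cur_sd > 0, cur_sd, 1.0), 0.0)
        xs = xs * scale + mu
        reps.append(pd.DataFrame(xs, index=Xf.index, columns=Xf.columns))
    return MSRSurrogates(replicates=reps, method="sign-flip", seed=seed)
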