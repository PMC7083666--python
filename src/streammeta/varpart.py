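"""Variation partitioning of community composition between environment and space.

Community abundances are Hellinger transformed and regressed (redundancy
analysis) on an environmental block E and a spatial block M of Moran
eigenvectors.  The explained variation splits into four fractions:

    [E|S]  unique environmental      = [E+S] - [S]
    [S|E]  unique spatial            = [E+S] - [E]
    [E^S]  spatially structured env. = [E] + [S] - [E+S]
    resid                            = 1 - [E+S]

computed from *adjusted* R^2 values.  Two adjustments are provided:

* classical — Ezekiel's 1 - (1-R^2)(n-1)/(n-p-1);
* msr — the null expectation of R^2 under Moran-spectral-randomization
  surrogates of the environmental block replaces the Ezekiel correction,
  1 - (1-R^2)/(1-mean(null R^2)).  This removes the spurious shared
  fraction that classical partitioning attributes to [E^S] when E and the
  community are independently spatially autocorrelated.

The difference delta = [E|S] - [S|E] summarizes the relative dominance of
environmental versus spatial control.  Because a larger taxon pool inflates
adjusted R^2, partitions are compared across datasets after standardizing
the number of taxa: random subsets of S taxa are drawn repeatedly and the
partition recomputed on each subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial import MEMBasis, MSRSurrogates, msr_surrogates

__all__ = [
    "TransformedCommunity",
    "VarpartResult",
    "StandardizationConfig",
    "StandardizedVarpart",
    "hellinger",
    "log1p_env",
    "rda_r2",
    "adjust_r2_classical",
    "adjust_r2_msr",
    "varpart",
    "standardized_varpart",
    "subset_by_trait",
]


def _abundance(community) -> pd.DataFrame:
    ab = community.abundance if hasattr(community, "abundance") else community
    if (ab.to_numpy(float) < 0).any():
        raise ValueError("abundances must be non-negative")
    return ab


@dataclass
class TransformedCommunity:
    """Hellinger-transformed site-by-taxon matrix (unit row sums of squares)."""

    data: pd.DataFrame
    source: str = "abundance"

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(float)

    @property
    def index(self):
        return self.data.index


def hellinger(raw) -> TransformedCommunity:
    """Hellinger transform: y'_ij = sqrt(y_ij / row_total_i).

    Rows with zero total are rejected (their site ids are listed).
    """
    ab = _abundance(raw)
    a = ab.to_numpy(float)
    totals = a.sum(axis=1)
    zero = list(ab.index[totals == 0])
    if zero:
        raise ValueError(f"sites with zero total abundance: {zero}")
    out = np.sqrt(a / totals[:, None])
    return TransformedCommunity(pd.DataFrame(out, index=ab.index, columns=ab.columns))


def log1p_env(env: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """log(X+1) transform of environmental variables, then column z-scores.

    Standardization makes forward selection and R^2 scale-free; it does not
    change the R^2 of a full block.  Entries <= -1 are rejected.
    """
    a = env.to_numpy(float)
    if (a <= -1).any():
        raise ValueError("log1p_env requires all entries > -1")
    out = np.log1p(a)
    if standardize:
        mu = out.mean(axis=0)
        sd = out.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        out = (out - mu) / sd
    return pd.DataFrame(out, index=env.index, columns=env.columns)


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _predictors(x) -> np.ndarray:
    if isinstance(x, TransformedCommunity):
        x = x.data
    a = x.to_numpy(float) if isinstance(x, (pd.DataFrame, pd.Series)) else np.asarray(x, float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def rda_r2(Y, X) -> float:
    """Unadjusted redundancy-analysis R^2 of Y on X.

    Equals trace(Yhat' Yhat) / trace(Yc' Yc) with Yhat the least-squares
    projection of the column-centered response on the column-centered
    predictors (equivalently the per-taxon regression sums of squares,
    summed).  Collinear predictor columns are harmless (lstsq uses the
    minimum-norm solution; the projection is unique).
    """
    ya = _predictors(Y)
    xa = _predictors(X)
    n = ya.shape[0]
    if n <= xa.shape[1] + 1:
        # more predictors than residual df: projection may be saturated
        pass
    yc = _center(ya)
    ss_tot = float(np.sum(yc * yc))
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    xc = _center(xa)
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fit = xc @ coef
    return float(np.sum(fit * fit) / ss_tot)


def adjust_r2_classical(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjustment 1 - (1-R^2)(n-1)/(n-p-1); p = 0 returns R^2."""
    if p == 0:
        return r2
    if n - p - 1 <= 0:
        raise ValueError("n - p - 1 must be positive")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def adjust_r2_msr(r2: float, null_r2s) -> float:
    """MSR adjustment 1 - (1-R^2)/(1-mean(null R^2)).

    ``null_r2s`` are R^2 values of the same model with MSR surrogates of
    the environmental block (>= 99 required).
    """
    null_r2s = np.asarray(list(null_r2s), float)
    if null_r2s.size < 99:
        raise ValueError("need >= 99 surrogate R^2 values")
    m = float(null_r2s.mean())
    if m >= 1:
        raise ValueError("mean null R^2 >= 1; adjustment undefined")
    return 1.0 - (1.0 - r2) / (1.0 - m)


@dataclass
class VarpartResult:
    """Adjusted variation-partitioning fractions for one community."""

    env_total: float          # [E]
    spatial_total: float      # [S]
    joint: float              # [E+S]
    unique_env: float         # [E|S]
    unique_spatial: float     # [S|E]
    shared: float             # [E^S]
    residual: float
    adjustment: str
    n_sites: int
    p_env: int
    p_spatial: int
    n_surrogates: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def delta(self) -> float:
        """[E|S] - [S|E]: positive when environmental control dominates."""
        return self.unique_env - self.unique_spatial

    def identity_gap(self) -> float:
        return abs(self.unique_env + self.unique_spatial + self.shared + self.residual - 1.0)

    def fractions(self) -> dict:
        return {
            "E": self.env_total, "S": self.spatial_total, "ES_joint": self.joint,
            "E|S": self.unique_env, "S|E": self.unique_spatial,
            "EintS": self.shared, "residual": self.residual, "delta": self.delta,
        }


def varpart(
    Y,
    E,
    M,
    adjustment: str = "classical",
    *,
    surrogates: MSRSurrogates | None = None,
    basis: MEMBasis | None = None,
    n_surrogates: int = 199,
    seed: int | None = None,
    clip_negative: bool = False,
) -> VarpartResult:
    """Partition the variation of Y between environment E and space M.

    Parameters
    ----------
    Y : TransformedCommunity (or numeric site-by-taxon frame/array).
    E : selected environmental columns (site-by-variable).
    M : selected spatial eigenvectors (site-by-vector).
    adjustment : ``"classical"`` (Ezekiel) or ``"msr"``.
    surrogates : precomputed MSR surrogates of E; otherwise generated from
        ``basis`` with ``n_surrogates`` replicates.  The spatial block is
        held fixed inside joint-model null R^2 computations.
    clip_negative : report negative adjusted fractions clipped to 0 (for
        display; the algebraic identity is preserved only unclipped).
    """
    ya = _predictors(Y)
    ea = _predictors(E)
    ma = _predictors(M)
    n = ya.shape[0]
    if ea.shape[1] < 1 or ma.shape[1] < 1:
        raise ValueError("E and M must each have at least one column")
    if ea.shape[0] != n or ma.shape[0] != n:
        raise ValueError("Y, E and M must cover the same sites")
    # Ezekiel's p counts effective (linearly independent) predictors, so
    # duplicated or collinear columns do not distort the adjustment
    p_e = int(np.linalg.matrix_rank(_center(ea)))
    p_s = int(np.linalg.matrix_rank(_center(ma)))
    p_es = int(np.linalg.matrix_rank(_center(np.column_stack([ea, ma]))))
    if n - p_es - 1 <= 0:
        raise ValueError("combined predictors exhaust the degrees of freedom")

    r2_e = rda_r2(ya, ea)
    r2_s = rda_r2(ya, ma)
    r2_es = rda_r2(ya, np.column_stack([ea, ma]))

    if adjustment == "classical":
        adj_e = adjust_r2_classical(r2_e, n, p_e)
        adj_s = adjust_r2_classical(r2_s, n, p_s)
        adj_es = adjust_r2_classical(r2_es, n, p_es)
        n_surr = 0
    elif adjustment == "msr":
        if surrogates is None:
            if basis is None:
                raise ValueError("msr adjustment needs `surrogates` or a MEM `basis`")
            E_frame = E if isinstance(E, pd.DataFrame) else pd.DataFrame(ea)
            surrogates = msr_surrogates(E_frame, basis, T=n_surrogates, seed=seed)
        null_e, null_es = [], []
        for rep in surrogates:
            ra = _predictors(rep)
            null_e.append(rda_r2(ya, ra))
            null_es.append(rda_r2(ya, np.column_stack([ra, ma])))
        # [E] from the env-only model; the joint model with surrogate E and the
        # spatial block held fixed isolates the unique environmental fraction
        # (the surrogates keep E's spatial structure but break its alignment
        # with Y, so everything the real E adds beyond that null is [E|S]).
        adj_e = adjust_r2_msr(r2_e, null_e)
        unique_env_msr = adjust_r2_msr(r2_es, null_es)
        adj_s = adjust_r2_classical(r2_s, n, p_s)  # no env block to randomize
        adj_es = adj_s + unique_env_msr
        n_surr = len(surrogates)
    else:
        raise ValueError("adjustment must be 'classical' or 'msr'")

    unique_env = adj_es - adj_s
    unique_spatial = adj_es - adj_e
    shared = adj_e + adj_s - adj_es
    residual = 1.0 - adj_es
    if clip_negative:
        unique_env, unique_spatial, shared = (
            max(0.0, unique_env), max(0.0, unique_spatial), max(0.0, shared))
    return VarpartResult(
        env_total=adj_e, spatial_total=adj_s, joint=adj_es,
        unique_env=unique_env, unique_spatial=unique_spatial,
        shared=shared, residual=residual, adjustment=adjustment,
        n_sites=n, p_env=p_e, p_spatial=p_s, n_surrogates=n_surr,
    )


@dataclass
class StandardizationConfig:
    """Taxon-count standardization: S taxa per replicate, n_reps replicates."""

    S: int = 20
    n_reps: int = 500
    seed: int | None = None


@dataclass
class StandardizedVarpart:
    """Distribution of the partition over taxon-standardized replicates."""

    deltas: np.ndarray
    results: list[VarpartResult]
    S: int
    n_redrawn: int

    @property
    def median_delta(self) -> float:
        return float(np.median(self.deltas))

    @property
    def iqr(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.deltas, [25, 75])
        return float(q1), float(q3)

    def boxplot_stats(self) -> dict:
        """Median, quartiles and Tukey fences (1.5 x IQR) of delta."""
        q1, q3 = self.iqr
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = self.deltas[(self.deltas >= lo) & (self.deltas <= hi)]
        return {
            "median": self.median_delta, "q1": q1, "q3": q3,
            "whisker_low": float(inside.min()) if inside.size else np.nan,
            "whisker_high": float(inside.max()) if inside.size else np.nan,
            "n_outliers": int(self.deltas.size - inside.size),
        }


def standardized_varpart(
    raw,
    E,
    M,
    cfg: StandardizationConfig,
    adjustment: str = "classical",
    *,
    basis: MEMBasis | None = None,
    n_surrogates: int = 199,
) -> StandardizedVarpart:
    """Repeat the partition on random subsets of ``cfg.S`` taxa.

    Each replicate draws S taxon columns without replacement from the raw
    abundance matrix, re-applies the Hellinger transform to the subset and
    runs :func:`varpart`.  A replicate in which some site loses all sampled
    taxa (zero row total) is discarded and redrawn; the count of redraws is
    reported.
    """
    ab = _abundance(raw)
    t = ab.shape[1]
    if cfg.S > t:
        raise ValueError(f"S={cfg.S} exceeds the {t} available taxa")
    if cfg.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    deltas, results = [], []
    n_redrawn = 0
    surrogates = None
    if adjustment == "msr":
        if basis is None:
            raise ValueError("msr adjustment needs a MEM basis")
        E_frame = E if isinstance(E, pd.DataFrame) else pd.DataFrame(_predictors(E))
        surrogates = msr_surrogates(
            E_frame, basis, T=n_surrogates,
            seed=None if cfg.seed is None else cfg.seed + 7919)
    for _ in range(cfg.n_reps):
        for _attempt in range(1000):
            cols = rng.choice(t, size=cfg.S, replace=False)
            sub = ab.iloc[:, np.sort(cols)]
            if (sub.sum(axis=1) > 0).all():
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a taxon subset without empty sites")
        res = varpart(hellinger(sub), E, M, adjustment, surrogates=surrogates)
        deltas.append(res.delta)
        results.append(res)
    return StandardizedVarpart(np.asarray(deltas), results, cfg.S, n_redrawn)


def subset_by_trait(raw, traits: pd.DataFrame, trait: str, cls: str):
    """Keep taxa whose family carries the requested dispersal-trait class.

    ``traits`` maps families to {low, high} classes for each trait column.
    Taxa from families absent from the table are dropped (their count is
    reported via the returned object's ``n_excluded``).  An empty result is
    rejected.
    """
    from .simulate import CommunityMatrix  # local import to avoid a cycle

    if not hasattr(raw, "family") or raw.family is None:
        raise ValueError("community has no family labels; cannot subset by trait")
    if trait not in traits.columns:
        raise ValueError(f"trait {trait!r} not in trait table columns {list(traits.columns)}")
    if cls not in ("low", "high"):
        raise ValueError("class must be 'low' or 'high'")
    fam_class = traits[trait]
    families = raw.family
    listed = families.isin(fam_class.index)
    matching = listed & (families.map(fam_class) == cls)
    kept = raw.abundance.loc[:, matching.values]
    if kept.shape[1] == 0:
        raise ValueError(
            f"no taxa left after subsetting to {trait}={cls} "
            f"({int((~listed).sum())} taxa from unlisted families excluded)")
    return CommunityMatrix(
        abundance=kept,
        family=families[matching.values],
        n_excluded=int((~listed).sum()),
    )
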