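"""Metacommunity connectivity index.

Connectivity of a focal site i is the distance-discounted fraction of the
site-pair taxon pool present at each surrounding site, averaged over the
n-1 surrounding sites:

    Con_i = 1/(n-1) * sum_{j != i} ( sum_{k in pool(i,j)} p_jk / m_ij ) * exp(-d_ij)

where pool(i, j) is the set of taxa present at site i or site j,
m_ij = |pool(i, j)|, p_jk is the presence (0/1) of taxon k at site j, and
d_ij is a route distance in km.  Each per-pair term lies in [0, 1], so
Con_i is in [0, 1]; a pair with an empty pool contributes 0.  The
metacommunity-level index Avg.Con is the mean of the Con_i.

Abundances are binarized (presence = abundance > 0) before use; the index
is therefore invariant to abundance magnitude and to taxon relabeling, and
is monotone non-increasing in every pairwise distance.

The normalization 1/m is defined per site pair; ``m_placement="per_focal"``
instead applies a single pool size per focal site (all taxa present at the
focal site or any surrounding site), for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConnectivityResult", "site_connectivity", "average_connectivity"]


@dataclass
class ConnectivityResult:
    """Per-site connectivities and their average for one route distance."""

    con: pd.Series            # Con_i per site (dimensionless)
    avg_con: float            # mean of con
    route: str                # distance metric used (GEO/TOP/WAT or "custom")
    n_sites: int
    pair_pool_sizes: pd.DataFrame  # m_ij per site pair

    def to_frame(self) -> pd.DataFrame:
        return self.con.rename("con").to_frame()


def _presence(community) -> pd.DataFrame:
    ab = community.abundance if hasattr(community, "abundance") else community
    a = ab.to_numpy(float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    return pd.DataFrame((a > 0).astype(float), index=ab.index, columns=ab.columns)


def _check_distances(d: pd.DataFrame, sites) -> np.ndarray:
    d = d.loc[sites, sites]
    a = d.to_numpy(float)
    bad = np.argwhere(np.isnan(a))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"missing distance between sites {d.index[i]!r} and {d.columns[j]!r}; "
            "connectivity needs a complete matrix — consider the GEO route"
        )
    if (a < 0).any():
        raise ValueError("distances must be non-negative")
    return a


def site_connectivity(
    community,
    d: pd.DataFrame,
    focal,
    m_placement: str = "per_pair",
) -> float:
    """Connectivity Con_i of one focal site (see module docstring)."""
    res = average_connectivity(community, d, m_placement=m_placement)
    return float(res.con.loc[focal])


def average_connectivity(
    community,
    d: pd.DataFrame,
    route: str = "custom",
    m_placement: str = "per_pair",
) -> ConnectivityResult:
    """Compute Con_i for every site and their average Avg.Con.

    Parameters
    ----------
    community : CommunityMatrix or sites-by-taxa DataFrame (abundance or
        presence; binarized internally).
    d : complete symmetric site-by-site distance matrix in km.
    route : label recorded in the result (``GEO``/``TOP``/``WAT``).
    m_placement : ``"per_pair"`` (default; pool size m_ij inside the sum
        over surrounding sites) or ``"per_focal"`` (a single pool per focal
        site, the union of taxa over the focal and all surrounding sites).
    """
    if m_placement not in ("per_pair", "per_focal"):
        raise ValueError("m_placement must be 'per_pair' or 'per_focal'")
    pres = _presence(community)
    n = len(pres)
    if n < 2:
        raise ValueError("need at least 2 sites")
    a = _check_distances(d, pres.index)
    p = pres.to_numpy(float)           # n x t
    kern = np.exp(-a)
    np.fill_diagonal(kern, 0.0)

    # pool(i,j) presence union and pool sizes, all pairs at once
    union = (p[:, None, :] + p[None, :, :] > 0).astype(float)   # n x n x t
    m_pair = union.sum(axis=2)                                   # m_ij
    # taxa of the pair present at the surrounding site j
    present_at_j = np.einsum("ijt,jt->ij", union, p)
    con = np.empty(n)
    if m_placement == "per_pair":
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(m_pair > 0, present_at_j / np.where(m_pair > 0, m_pair, 1.0), 0.0)
        con = (frac * kern).sum(axis=1) / (n - 1)
    else:
        # literal reading: one 1/m factor outside the sum over j
        for i in range(n):
            pool = (p.sum(axis=0) > 0) | (p[i] > 0)
            m_i = float(pool.sum())
            if m_i == 0:
                con[i] = 0.0
                continue
            s = float(np.sum(p[:, pool] @ np.ones(int(m_i)) * kern[i]))
            con[i] = s / m_i / (n - 1)
    series = pd.Series(con, index=pres.index, name="con")
    return ConnectivityResult(
        con=series,
        avg_con=float(series.mean()),
        route=route,
        n_sites=n,
        pair_pool_sizes=pd.DataFrame(m_pair, index=pres.index, columns=pres.index),
    )
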