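"""Synthetic hierarchical stream metacommunities.

Three sampling designs mirror a nested stream hierarchy with 18 sites each:

* ``within_stream``  — all 18 sites on one dendritic (tree) channel network;
  every pair is connected by watercourse.  Small extent (~15 km).
* ``among_stream``   — one site in each of 18 streams of a single basin,
  joined through a common mainstem (optionally left disconnected).
  Intermediate extent (~60 km).
* ``among_subbasin`` — four sub-basins holding 7/5/4/2 streams (one site
  per stream); sub-basins may be connected through the basin mainstem or
  left as separate drainages (watercourse distance then missing across
  sub-basins).  Large extent (~250 km).

Default extents, base elevations and relief follow the magnitudes of the
three study scales (pairwise geographic distances of a few km, tens of km
and a couple hundred km respectively).

Communities assemble under one of three regimes, sampled with Poisson or
negative-binomial noise around an expectation built from Gaussian niche
responses to a spatially autocorrelated environment:

* ``species_sorting``     — expectation tracks the local environment only:
  E[y_ik] = M * exp(-sum_a (env_ia - mu_ka)^2 / (2 sigma^2)).
* ``mass_effects``        — the sorting expectation is redistributed by a
  wide dispersal kernel K_ij = exp(-d_ij / lambda) (row-normalized),
  homogenizing composition across sites.
* ``dispersal_limitation``— a flattened niche response (sigma inflated) is
  multiplied by per-taxon occupancy clusters spread from a random seed site
  with a narrow kernel, decoupling composition from the environment while
  creating spatial structure.

All randomness flows through one seeded generator per function, so a fixed
seed reproduces outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .geometry import (
    DistanceTriplet,
    FunctionSurface,
    StreamNetwork,
    geographic_distance,
    topographic_distance,
    watercourse_distance,
)
from .spatial import build_swm, compute_mem

__all__ = [
    "DesignConfig",
    "ScenarioConfig",
    "CommunityMatrix",
    "generate_design",
    "generate_environment",
    "generate_community",
    "generate_trait_table",
    "design_distances",
]

DESIGNS = ("within_stream", "among_stream", "among_subbasin")
REGIMES = ("species_sorting", "mass_effects", "dispersal_limitation")

_DESIGN_EXTENT = {"within_stream": 15.0, "among_stream": 60.0, "among_subbasin": 250.0}
_DESIGN_BASE_ELEV = {"within_stream": 2.2, "among_stream": 0.05, "among_subbasin": 0.1}
_DESIGN_RELIEF = {"within_stream": 0.6, "among_stream": 0.5, "among_subbasin": 1.2}
_DESIGN_TORTUOSITY = {"within_stream": (1.1, 1.4), "among_stream": (1.3, 1.9),
                      "among_subbasin": (1.3, 1.9)}


@dataclass
class DesignConfig:
    """Parameters of one hierarchical sampling design."""

    design: str = "within_stream"
    n_sites: int = 18
    subbasin_sizes: tuple = (7, 5, 4, 2)
    extent: float | None = None      # km; per-design default if None
    seed: int | None = 0
    connect_subbasins: bool = True   # among_subbasin: join drainages?
    connect_streams: bool = True     # among_stream: common mainstem?

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if self.design == "among_subbasin":
            self.n_sites = int(sum(self.subbasin_sizes))
        if self.n_sites < 8:
            raise ValueError("n_sites must be >= 8")
        if self.extent is None:
            self.extent = _DESIGN_EXTENT[self.design]
        if self.extent <= 0:
            raise ValueError("extent must be > 0")


@dataclass
class ScenarioConfig:
    """Assembly-regime parameters for community generation."""

    regime: str = "species_sorting"
    n_taxa: int = 60
    niche_sigma: float = 1.0         # niche breadth per environmental axis
    n_niche_axes: int = 2            # leading env axes the niche responds to
    max_abundance: float = 50.0      # M, expected count at the niche optimum
    dispersal_scale: float | None = None  # lambda (km); per-regime default
    route: str = "GEO"               # distance metric feeding the kernel
    noise: str = "negative_binomial"  # 'poisson', 'negative_binomial', 'none'
    nb_k: float = 5.0                # NB overdispersion (var = mu + mu^2/k)
    background: float = 0.005        # vagrant expectation as a fraction of M
    env_decoupling: float = 5.0      # sigma inflation under dispersal limitation
    taxa_per_family: int = 3
    seed: int | None = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.n_taxa < 10:
            raise ValueError("n_taxa must be >= 10")
        if self.niche_sigma <= 0:
            raise ValueError("niche_sigma must be > 0")
        if self.dispersal_scale is not None and self.dispersal_scale <= 0:
            raise ValueError("dispersal_scale must be > 0")
        if self.noise not in ("poisson", "negative_binomial", "none"):
            raise ValueError("noise must be 'poisson', 'negative_binomial' or 'none'")


@dataclass
class CommunityMatrix:
    """Sites-by-taxa non-negative integer abundances with family labels."""

    abundance: pd.DataFrame
    family: pd.Series | None = None      # taxon id -> family id
    n_excluded: int = 0

    def __post_init__(self):
        a = self.abundance.to_numpy()
        if (a < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def n_sites(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.abundance.shape[1]

    def presence(self) -> pd.DataFrame:
        return (self.abundance > 0).astype(int)


# ---------------------------------------------------------------------------
# design generation
# ---------------------------------------------------------------------------


def _mst_tree(xy: np.ndarray) -> list[tuple[int, int]]:
    d = squareform(pdist(xy))
    t = minimum_spanning_tree(d).toarray()
    return [(int(i), int(j)) for i, j in zip(*np.nonzero(t))]


def _spread_points(rng, n, extent, lo=None, hi=None, min_frac=0.04, max_tries=200):
    """Uniform points in a box with a minimum mutual separation."""
    lo = np.zeros(2) if lo is None else np.asarray(lo, float)
    hi = np.full(2, extent) if hi is None else np.asarray(hi, float)
    span = np.min(hi - lo)
    min_sep = min_frac * span
    for _ in range(max_tries):
        pts = lo + rng.random((n, 2)) * (hi - lo)
        if n < 2 or pdist(pts).min() >= min_sep:
            return pts
    return pts  # fall back to the last draw


def _random_surface(rng, extent, base, relief, n_hills=6):
    """Smooth random elevation field: tilted plane plus Gaussian hills."""
    cx = rng.random(n_hills) * extent
    cy = rng.random(n_hills) * extent
    amp = relief * (0.3 + 0.7 * rng.random(n_hills))
    width = extent * (0.12 + 0.18 * rng.random(n_hills))
    tilt = rng.normal(0, 0.25 * relief / max(extent, 1e-9), size=2)

    def f(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        z = np.full(np.broadcast(x, y).shape, base, float)
        z = z + tilt[0] * x + tilt[1] * y
        for k in range(n_hills):
            z = z + amp[k] * np.exp(-(((x - cx[k]) ** 2 + (y - cy[k]) ** 2)
                                      / (2 * width[k] ** 2)))
        return np.maximum(z, 0.0)

    return FunctionSurface(f)


def _build_tree_network(g, xy, edges, rng, tort_range, base_elev, root=None):
    """Add nodes/edges for one tree; assign elevations increasing upstream."""
    offset = g.number_of_nodes()
    ids = [f"N{offset + k}" for k in range(len(xy))]
    lo, hi = tort_range
    for k, nid in enumerate(ids):
        g.add_node(nid, x=float(xy[k, 0]), y=float(xy[k, 1]), elevation=0.0)
    adj = {k: [] for k in range(len(xy))}
    for i, j in edges:
        euclid = float(np.hypot(*(xy[i] - xy[j])))
        length = euclid * float(lo + (hi - lo) * rng.random())
        g.add_edge(ids[i], ids[j], length=length)
        adj[i].append(j)
        adj[j].append(i)
    # outlet = lowest-index node unless given; elevation grows upstream
    root = 0 if root is None else root
    slope = 0.005 + 0.02 * rng.random()
    g.nodes[ids[root]]["elevation"] = base_elev
    stack = [root]
    seen = {root}
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if j not in seen:
                seen.add(j)
                length = g.edges[ids[i], ids[j]]["length"]
                g.nodes[ids[j]]["elevation"] = g.nodes[ids[i]]["elevation"] + slope * length
                stack.append(j)
    return ids


def generate_design(cfg: DesignConfig):
    """Generate ``(sites, network, surface)`` for one sampling design.

    Every site coincides with a network node; elevation decreases
    downstream along every channel.  The elevation surface is an analytic
    smooth random field over the design's bounding box, independent of the
    channel profile.
    """
    rng = np.random.default_rng(cfg.seed)
    extent = float(cfg.extent)
    g = nx.Graph()
    site_rows = []
    mapping = {}

    if cfg.design == "within_stream":
        xy = _spread_points(rng, cfg.n_sites, extent)
        ids = _build_tree_network(g, xy, _mst_tree(xy), rng,
                                  _DESIGN_TORTUOSITY[cfg.design],
                                  _DESIGN_BASE_ELEV[cfg.design])
        for k, nid in enumerate(ids):
            sid = f"S{k + 1:02d}"
            mapping[sid] = nid
            site_rows.append((sid, xy[k, 0], xy[k, 1], g.nodes[nid]["elevation"], "ST1", "SB1"))

    elif cfg.design == "among_stream":
        xy = _spread_points(rng, cfg.n_sites, extent)
        if cfg.connect_streams:
            ids = _build_tree_network(g, xy, _mst_tree(xy), rng,
                                      _DESIGN_TORTUOSITY[cfg.design],
                                      _DESIGN_BASE_ELEV[cfg.design])
        else:
            ids = []
            for k in range(cfg.n_sites):
                ids.extend(_build_tree_network(g, xy[k:k + 1], [], rng,
                                               _DESIGN_TORTUOSITY[cfg.design],
                                               _DESIGN_BASE_ELEV[cfg.design]))
        for k, nid in enumerate(ids):
            sid = f"S{k + 1:02d}"
            mapping[sid] = nid
            site_rows.append((sid, xy[k, 0], xy[k, 1], g.nodes[nid]["elevation"],
                              f"ST{k + 1}", "SB1"))

    else:  # among_subbasin
        n_sb = len(cfg.subbasin_sizes)
        n_cols = int(np.ceil(np.sqrt(n_sb)))
        boxes = []
        for b in range(n_sb):
            r, c = divmod(b, n_cols)
            n_rows = int(np.ceil(n_sb / n_cols))
            lo = np.array([c * extent / n_cols, r * extent / n_rows])
            hi = np.array([(c + 1) * extent / n_cols, (r + 1) * extent / n_rows])
            boxes.append((lo, hi))
        all_ids = []
        k_site = 0
        subbasin_node_ids = []
        all_xy = []
        for b, size in enumerate(cfg.subbasin_sizes):
            lo, hi = boxes[b]
            xy = _spread_points(rng, size, extent, lo=lo, hi=hi)
            edges = _mst_tree(xy) if size > 1 else []
            ids = _build_tree_network(g, xy, edges, rng,
                                      _DESIGN_TORTUOSITY[cfg.design],
                                      _DESIGN_BASE_ELEV[cfg.design])
            subbasin_node_ids.append(ids)
            all_ids.extend(ids)
            all_xy.append(xy)
            for k, nid in enumerate(ids):
                sid = f"S{k_site + 1:02d}"
                k_site += 1
                mapping[sid] = nid
                site_rows.append((sid, xy[k, 0], xy[k, 1], g.nodes[nid]["elevation"],
                                  f"ST{k_site}", f"SB{chr(ord('A') + b)}"))
        if cfg.connect_subbasins:
            # join sub-basin trees by the closest node pairs, MST over components
            centers = [xy.mean(axis=0) for xy in all_xy]
            comp_edges = _mst_tree(np.array(centers))
            lo_t, hi_t = _DESIGN_TORTUOSITY[cfg.design]
            for b1, b2 in comp_edges:
                best = None
                for n1 in subbasin_node_ids[b1]:
                    for n2 in subbasin_node_ids[b2]:
                        d = np.hypot(g.nodes[n1]["x"] - g.nodes[n2]["x"],
                                     g.nodes[n1]["y"] - g.nodes[n2]["y"])
                        if best is None or d < best[0]:
                            best = (d, n1, n2)
                d, n1, n2 = best
                g.add_edge(n1, n2, length=float(d * (lo_t + (hi_t - lo_t) * rng.random())))

    sites = pd.DataFrame(site_rows,
                         columns=["site_id", "x", "y", "elevation", "stream_id", "subbasin_id"])
    sites = sites.set_index("site_id")
    surface = _random_surface(rng, extent, _DESIGN_BASE_ELEV[cfg.design],
                              _DESIGN_RELIEF[cfg.design])
    # keep the site table's elevation consistent with the network profile;
    # the overland surface is a separate field used only for TOP distances
    net = StreamNetwork(graph=g, site_to_node=mapping)
    return sites, net, surface


def design_distances(sites, net, surface, step: float = 0.05) -> DistanceTriplet:
    """Convenience: the GEO/TOP/WAT triplet for a generated design."""
    geo = geographic_distance(sites)
    top = topographic_distance(sites, surface, step=step)
    # overland 3-D distance can fall below the straight-line only by roundoff
    wat = watercourse_distance(sites, net)
    return DistanceTriplet(geo=geo, top=top, wat=wat)


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def generate_environment(
    sites: pd.DataFrame,
    autocorr_range: float,
    n_vars: int = 10,
    seed: int | None = 0,
    noise_fraction: float = 0.2,
) -> pd.DataFrame:
    """Spatially autocorrelated environmental variables (mean 0, sd 1).

    Each variable is a weighted sum of the positive Moran eigenvectors of a
    Gabriel-graph SWM on the site coordinates, mixed with white noise.  The
    eigenvector weights decay with rank at a rate set by ``autocorr_range``
    (km): a range near 0 gives pure white noise (no spatial structure), a
    range comparable to the extent concentrates weight on the broadest
    eigenvector.  ``noise_fraction`` is the variance share of the white
    component when structure is at full strength.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if autocorr_range < 0:
        raise ValueError("autocorr_range must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(sites)
    geo = geographic_distance(sites)
    extent = float(np.nanmax(geo.to_numpy()))
    basis = compute_mem(build_swm(geo, "gabriel", "binary"))
    pos = basis.positive.to_numpy(float)
    out = np.empty((n, n_vars))
    # structure share grows with range relative to the extent
    struct = autocorr_range / (autocorr_range + 0.25 * extent) if extent > 0 else 0.0
    q = pos.shape[1]
    for v in range(n_vars):
        white = rng.standard_normal(n)
        if q == 0 or struct == 0.0:
            x = white
        else:
            # rank-decay of eigenvector weights: slower decay = broader field
            decay = np.exp(-np.arange(q) / max(q * struct, 1e-9))
            coeff = rng.standard_normal(q) * decay
            s = pos @ coeff
            s_sd = s.std()
            s = s / s_sd if s_sd > 0 else s
            amp = struct * np.sqrt(1.0 - noise_fraction)
            x = amp * s + np.sqrt(max(1.0 - amp**2, 0.0)) * white
        x = (x - x.mean()) / x.std(ddof=0)
        out[:, v] = x
    cols = [f"env{v + 1}" for v in range(n_vars)]
    return pd.DataFrame(out, index=sites.index, columns=cols)


# ---------------------------------------------------------------------------
# community
# ---------------------------------------------------------------------------


def _default_lambda(regime: str, extent: float) -> float:
    if regime == "mass_effects":
        return 2.0 * extent
    if regime == "dispersal_limitation":
        return extent / 6.0
    return extent / 2.0  # species sorting: kernel unused


def generate_community(
    sites: pd.DataFrame,
    env: pd.DataFrame,
    distances: DistanceTriplet | pd.DataFrame,
    scenario: ScenarioConfig,
) -> CommunityMatrix:
    """Draw a site-by-taxon count matrix under an assembly regime.

    See the module docstring for the three regimes.  Taxa are labeled
    ``t001..`` and grouped into families of ``taxa_per_family`` consecutive
    taxa.  All-zero taxon columns are removed after sampling.
    """
    rng = np.random.default_rng(scenario.seed)
    if isinstance(distances, DistanceTriplet):
        d = distances[scenario.route].to_numpy(float)
    else:
        d = distances.to_numpy(float)
    if np.isnan(d).any() and scenario.regime != "species_sorting":
        raise ValueError(
            f"dispersal kernel over missing {scenario.route} distances; "
            "use route='GEO' (always complete) or a connected network")
    e = env.loc[sites.index].to_numpy(float)
    n, _ = e.shape
    t = scenario.n_taxa
    axes = min(scenario.n_niche_axes, e.shape[1])
    ea = e[:, :axes]
    geo_extent = float(np.nanmax(d)) if np.isfinite(np.nanmax(d)) else 1.0
    lam = scenario.dispersal_scale or _default_lambda(scenario.regime, geo_extent)

    sigma = scenario.niche_sigma
    if scenario.regime == "dispersal_limitation":
        sigma = sigma * scenario.env_decoupling
    # niche optima spread over the realized environmental range per axis
    mu = np.column_stack([
        rng.uniform(ea[:, a].min(), ea[:, a].max(), size=t) for a in range(axes)
    ])
    sq = ((ea[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    expect = scenario.max_abundance * np.exp(-sq / (2.0 * sigma**2))

    if scenario.regime == "mass_effects":
        kern = np.exp(-d / lam)
        kern = kern / kern.sum(axis=1, keepdims=True)
        expect = kern @ expect
    elif scenario.regime == "dispersal_limitation":
        seeds = rng.integers(0, n, size=t)
        reach = np.exp(-d[:, seeds] / lam)          # n x t occupancy probability
        occ = (rng.random((n, t)) < reach).astype(float)
        occ[seeds, np.arange(t)] = 1.0              # the seed site is always occupied
        expect = expect * occ

    expect = expect + scenario.background * scenario.max_abundance

    if scenario.noise == "poisson":
        counts = rng.poisson(expect)
    elif scenario.noise == "negative_binomial":
        shape = scenario.nb_k
        lam_nb = rng.gamma(shape, expect / shape)
        counts = rng.poisson(lam_nb)
    else:  # deterministic expectation, round-half-to-even
        counts = np.rint(expect).astype(np.int64)

    taxa = [f"t{k + 1:03d}" for k in range(t)]
    fam = pd.Series(
        [f"F{k // scenario.taxa_per_family + 1:02d}" for k in range(t)],
        index=taxa, name="family")
    ab = pd.DataFrame(counts.astype(np.int64), index=sites.index, columns=taxa)
    nonzero = ab.sum(axis=0) > 0
    ab = ab.loc[:, nonzero]
    fam = fam[nonzero.values]
    return CommunityMatrix(abundance=ab, family=fam)


def generate_trait_table(
    families,
    p_high: float = 0.5,
    seed: int | None = 0,
    traits=("drifting_propensity", "female_dispersal"),
) -> pd.DataFrame:
    """Assign each family a {low, high} class per dispersal trait.

    Classes are independent Bernoulli(``p_high``) draws per family and
    trait.  ``families`` may be a CommunityMatrix, a family Series, or an
    iterable of family ids.
    """
    if not 0.0 <= p_high <= 1.0:
        raise ValueError("p_high must lie in [0, 1]")
    if hasattr(families, "family") and families.family is not None:
        fam_ids = pd.unique(families.family)
    elif isinstance(families, pd.Series):
        fam_ids = pd.unique(families)
    else:
        fam_ids = pd.unique(pd.Series(list(families)))
    rng = np.random.default_rng(seed)
    data = {
        tr: np.where(rng.random(len(fam_ids)) < p_high, "high", "low")
        for tr in traits
    }
    return pd.DataFrame(data, index=pd.Index(fam_ids, name="family"))
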