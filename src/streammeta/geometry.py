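"""Sites on dendritic stream networks and the three dispersal-route distances.

Sites live in planar km coordinates (project before input; no geodesy here).
Three pairwise distance metrics describe alternative dispersal pathways:

* geographic (GEO)  — straight-line Euclidean distance,
* topographic (TOP) — 3-D overland distance across the elevation surface,
  integrated along the straight horizontal segment between the sites,
* watercourse (WAT) — shortest-path distance along the stream channels.

TOP and WAT are never shorter than GEO.  Site pairs in distinct drainage
basins have no watercourse route; such entries are reported as missing
(NaN), never as infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.distance import pdist, squareform

SITE_COLUMNS = ["site_id", "x", "y", "elevation", "stream_id", "subbasin_id"]

__all__ = [
    "SITE_COLUMNS",
    "validate_sites",
    "read_sites",
    "StreamNetwork",
    "ElevationSurface",
    "FunctionSurface",
    "GridSurface",
    "DistanceTriplet",
    "geographic_distance",
    "topographic_distance",
    "watercourse_distance",
    "summarize_distances",
]


def validate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Validate a site table (columns ``site_id,x,y,elevation,stream_id,subbasin_id``).

    Returns the table indexed by ``site_id``.  Raises ``ValueError`` on
    duplicate ids, non-finite coordinates or negative elevation.
    """
    df = sites.copy()
    if df.index.name == "site_id":
        df = df.reset_index()
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table is missing columns {missing}")
    dup = df["site_id"][df["site_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate site_id values: {dup}")
    xy = df[["x", "y", "elevation"]].to_numpy(float)
    if not np.isfinite(xy).all():
        raise ValueError("site coordinates and elevations must be finite")
    if (df["elevation"].to_numpy(float) < 0).any():
        raise ValueError("elevation must be >= 0 km")
    return df.set_index("site_id")


def read_sites(path) -> pd.DataFrame:
    """Read a site table CSV and validate it."""
    return validate_sites(pd.read_csv(path, dtype={"site_id": str}))


# ---------------------------------------------------------------------------
# elevation surfaces
# ---------------------------------------------------------------------------

ElevationSurface = Callable[[np.ndarray, np.ndarray], np.ndarray]
"""A function ``(x, y) -> elevation`` (km), vectorized over arrays."""


class FunctionSurface:
    """Elevation surface given analytically as ``z = f(x, y)``."""

    def __init__(self, func: Callable[[np.ndarray, np.ndarray], np.ndarray]):
        self._func = func

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.asarray(self._func(np.asarray(x, float), np.asarray(y, float)), float)


class GridSurface:
    """Elevation raster with bilinear interpolation.

    Parameters
    ----------
    x_grid, y_grid : 1-D ascending coordinate vectors (km).
    z : 2-D elevation array of shape ``(len(x_grid), len(y_grid))`` (km).

    Evaluation outside the grid raises ``ValueError`` (callers flag the
    affected distance entries as missing).
    """

    def __init__(self, x_grid: np.ndarray, y_grid: np.ndarray, z: np.ndarray):
        self._interp = RegularGridInterpolator(
            (np.asarray(x_grid, float), np.asarray(y_grid, float)),
            np.asarray(z, float),
            method="linear",
            bounds_error=True,
        )

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        pts = np.column_stack([np.ravel(x), np.ravel(y)])
        return self._interp(pts).reshape(np.shape(x))


# ---------------------------------------------------------------------------
# stream network
# ---------------------------------------------------------------------------


@dataclass
class StreamNetwork:
    """An undirected stream-channel graph with sites snapped to nodes.

    ``graph`` nodes carry ``x, y, elevation`` attributes; edges carry
    ``length`` (channel km, at least the Euclidean distance between the
    endpoints).  ``site_to_node`` maps each site id to exactly one node.
    """

    graph: nx.Graph
    site_to_node: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if data.get("length") is None:
                raise ValueError(f"edge ({u}, {v}) has no length")
            eu = _node_xy(self.graph, u)
            ev = _node_xy(self.graph, v)
            euclid = float(np.hypot(*(eu - ev)))
            if data["length"] < euclid - 1e-9:
                raise ValueError(
                    f"edge ({u}, {v}) length {data['length']:.4f} km is shorter "
                    f"than the straight-line distance {euclid:.4f} km"
                )

    @classmethod
    def from_frames(
        cls,
        nodes: pd.DataFrame,
        edges: pd.DataFrame,
        sites: pd.DataFrame | None = None,
        snap_tolerance: float = 0.1,
    ) -> "StreamNetwork":
        """Build a network from node (``node_id,x,y,elevation``) and edge
        (``node_a,node_b,length``) tables, snapping sites to their nearest node.

        A site farther than ``snap_tolerance`` km from every node is rejected.
        """
        g = nx.Graph()
        for rec in nodes.itertuples(index=False):
            g.add_node(rec.node_id, x=float(rec.x), y=float(rec.y),
                       elevation=float(getattr(rec, "elevation", 0.0)))
        for rec in edges.itertuples(index=False):
            g.add_edge(rec.node_a, rec.node_b, length=float(rec.length))
        mapping: dict[str, object] = {}
        if sites is not None:
            sites = validate_sites(sites) if sites.index.name != "site_id" else sites
            node_ids = list(g.nodes)
            node_xy = np.array([[g.nodes[n]["x"], g.nodes[n]["y"]] for n in node_ids])
            for sid, row in sites.iterrows():
                d = np.hypot(node_xy[:, 0] - row["x"], node_xy[:, 1] - row["y"])
                k = int(np.argmin(d))
                if d[k] > snap_tolerance:
                    raise ValueError(
                        f"site {sid!r} is {d[k]:.3f} km from the nearest network "
                        f"node, beyond the snap tolerance {snap_tolerance} km"
                    )
                mapping[sid] = node_ids[k]
        return cls(graph=g, site_to_node=mapping)

    def node_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (nodes, edges) tables in the CSV interchange schema."""
        nodes = pd.DataFrame(
            [
                {"node_id": n, "x": d["x"], "y": d["y"], "elevation": d.get("elevation", 0.0)}
                for n, d in self.graph.nodes(data=True)
            ]
        )
        edges = pd.DataFrame(
            [{"node_a": u, "node_b": v, "length": d["length"]} for u, v, d in self.graph.edges(data=True)]
        )
        return nodes, edges


def _node_xy(g: nx.Graph, n) -> np.ndarray:
    d = g.nodes[n]
    return np.array([d["x"], d["y"]], float)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _as_matrix(values: np.ndarray, sites: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(values, index=sites.index, columns=sites.index)


def geographic_distance(sites: pd.DataFrame) -> pd.DataFrame:
    """Straight-line Euclidean distance (km) between all site pairs."""
    sites = validate_sites(sites) if sites.index.name != "site_id" else sites
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    xy = sites[["x", "y"]].to_numpy(float)
    return _as_matrix(squareform(pdist(xy)), sites)


def topographic_distance(
    sites: pd.DataFrame,
    surface: ElevationSurface,
    step: float = 0.01,
) -> pd.DataFrame:
    """Overland 3-D distance (km) across the elevation surface.

    The straight horizontal segment between each site pair is sampled at a
    spacing of at most ``step`` km and the 3-D polyline length
    ``sum(sqrt(dh^2 + dz^2))`` is accumulated.  Always >= the geographic
    distance.  Pairs whose segment leaves the surface's domain get NaN.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    sites = validate_sites(sites) if sites.index.name != "site_id" else sites
    xy = sites[["x", "y"]].to_numpy(float)
    n = len(sites)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            horiz = float(np.hypot(*(xy[i] - xy[j])))
            if horiz == 0.0:
                continue
            n_seg = max(1, int(np.ceil(horiz / step)))
            t = np.linspace(0.0, 1.0, n_seg + 1)
            px = xy[i, 0] + t * (xy[j, 0] - xy[i, 0])
            py = xy[i, 1] + t * (xy[j, 1] - xy[i, 1])
            try:
                z = np.asarray(surface(px, py), float)
            except ValueError:
                out[i, j] = out[j, i] = np.nan
                continue
            dh = horiz / n_seg
            dz = np.diff(z)
            d = float(np.sum(np.sqrt(dh * dh + dz * dz)))
            out[i, j] = out[j, i] = d
    return _as_matrix(out, sites)


def watercourse_distance(sites: pd.DataFrame, net: StreamNetwork) -> pd.DataFrame:
    """Shortest-path channel distance (km) between sites along the network.

    Pairs in disconnected components (distinct drainage basins) are NaN.
    """
    sites = validate_sites(sites) if sites.index.name != "site_id" else sites
    unmapped = [sid for sid in sites.index if sid not in net.site_to_node]
    if unmapped:
        raise ValueError(f"sites not mapped to network nodes: {unmapped}")
    n = len(sites)
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 0.0)
    nodes = [net.site_to_node[sid] for sid in sites.index]
    for i, src in enumerate(nodes):
        lengths = nx.single_source_dijkstra_path_length(net.graph, src, weight="length")
        for j, dst in enumerate(nodes):
            if dst in lengths:
                out[i, j] = lengths[dst]
    out = np.minimum(out, out.T)  # enforce exact symmetry
    return _as_matrix(out, sites)


@dataclass
class DistanceTriplet:
    """The three site-by-site route distance matrices (km): GEO, TOP, WAT."""

    geo: pd.DataFrame
    top: pd.DataFrame
    wat: pd.DataFrame

    ROUTES = ("GEO", "TOP", "WAT")

    def __post_init__(self) -> None:
        for name, m in self.items():
            a = m.to_numpy(float)
            if not np.allclose(np.diag(a), 0.0):
                raise ValueError(f"{name} matrix has a nonzero diagonal")
            if not np.allclose(a, a.T, equal_nan=True):
                raise ValueError(f"{name} matrix is not symmetric")
        geo = self.geo.to_numpy(float)
        for name in ("TOP", "WAT"):
            other = self[name].to_numpy(float)
            ok = np.isnan(other) | (other >= geo - 1e-9)
            if not ok.all():
                raise ValueError(f"{name} must be >= GEO elementwise")

    def __getitem__(self, route: str) -> pd.DataFrame:
        route = route.upper()
        if route not in self.ROUTES:
            raise KeyError(f"unknown route {route!r}; expected one of {self.ROUTES}")
        return {"GEO": self.geo, "TOP": self.top, "WAT": self.wat}[route]

    def items(self):
        return zip(self.ROUTES, (self.geo, self.top, self.wat))


def summarize_distances(triplet: DistanceTriplet) -> pd.DataFrame:
    """Mean, min, max and sample sd (n-1) over unordered off-diagonal pairs.

    Missing entries are excluded and counted in ``n_missing``.  A metric with
    no observed pair is rejected.
    """
    rows = []
    for name, m in triplet.items():
        a = m.to_numpy(float)
        if a.shape[0] < 2:
            raise ValueError("need at least 2 sites")
        iu = np.triu_indices(a.shape[0], k=1)
        vals = a[iu]
        obs = vals[~np.isnan(vals)]
        if obs.size == 0:
            raise ValueError(f"all {name} pairs are missing")
        sd = float(np.std(obs, ddof=1)) if obs.size > 1 else 0.0
        rows.append(
            {
                "metric": name,
                "mean": float(obs.mean()),
                "min": float(obs.min()),
                "max": float(obs.max()),
                "sd": sd,
                "n_pairs": int(obs.size),
                "n_missing": int(vals.size - obs.size),
            }
        )
    return pd.DataFrame(rows).set_index("metric")
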