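"""Pedestrian network: graph construction, slope-aware impedance, distance fields.

The pedestrian network is an undirected graph of every walkable path segment,
with metric edge lengths and unsigned percent gradients. It is the impedance
substrate for all proximity computations: a *distance field* assigns every
node its shortest network distance (meters, or walking minutes) to the
nearest of a set of source points (benches, facilities), computed with a
multi-source Dijkstra. Sources that fall mid-edge split the edge
proportionally rather than being rounded to a node.

Walking speed follows a two-regime model for older adults: a moderate pace on
gentle slopes and a slower pace once the gradient passes 9 degrees
(~15.84 percent). Gradients are unsigned — walking up and down a slope are
treated as equally costly — which keeps the graph undirected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point

from .terrain import ElevationRaster

__all__ = [
    "SpeedModel",
    "PedestrianNetwork",
    "DistanceField",
    "EdgePosition",
    "UNREACHABLE",
    "build_network",
    "assign_gradients",
    "walking_speed",
    "traversal_time",
    "snap_point",
    "distance_field",
]

#: Sentinel for nodes that no source can reach.
UNREACHABLE = math.inf

#: Node-merge tolerance when building the graph (m).
DEFAULT_SNAP_TOLERANCE = 0.05
#: Default radius within which off-network points snap to an edge (m).
DEFAULT_SNAP_RADIUS = 25.0


@dataclass(frozen=True)
class SpeedModel:
    """Two-regime walking speed: ``moderate_speed`` up to and including
    ``gradient_threshold`` percent, ``steep_speed`` beyond it.

    Defaults average published older-adult speed profiles into 4.3 km/h on
    gradients up to 9 degrees and 4.0 km/h on steeper ones; the threshold is
    stored in percent (tan 9deg x 100 ~= 15.84)."""

    moderate_speed: float = 4.3
    steep_speed: float = 4.0
    gradient_threshold: float = 100.0 * math.tan(math.radians(9.0))

    def __post_init__(self) -> None:
        if not (self.moderate_speed > 0 and self.steep_speed > 0):
            raise ValueError("speeds must be positive")
        if self.moderate_speed < self.steep_speed:
            raise ValueError("moderate speed must be >= steep speed")
        if not self.gradient_threshold > 0:
            raise ValueError("gradient threshold must be positive")


def walking_speed(gradient: float, model: SpeedModel | None = None) -> float:
    """Walking speed (km/h) for an unsigned percent gradient."""
    if gradient < 0:
        raise ValueError(
            f"gradient must be non-negative (pass |gradient|), got {gradient}"
        )
    model = model or SpeedModel()
    return model.moderate_speed if gradient <= model.gradient_threshold else model.steep_speed


def traversal_time(length: float, gradient: float, model: SpeedModel | None = None) -> float:
    """Minutes to walk ``length`` meters at the speed for ``gradient``."""
    if length < 0:
        raise ValueError(f"length must be non-negative, got {length}")
    speed_m_per_min = walking_speed(gradient, model) * 1000.0 / 60.0
    return length / speed_m_per_min


class PedestrianNetwork:
    """Undirected walkable graph with planar node coordinates in meters.

    Thin wrapper over a ``networkx.Graph``; nodes are integer ids carrying
    ``x``/``y`` (and optionally ``elevation``), edges carry ``length`` (m),
    ``gradient`` (unsigned %), ``walkable``, a stable integer ``eid`` and the
    full polyline ``geom``.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self._edge_order: list[tuple[int, int]] = []

    # -- construction ------------------------------------------------------

    def add_node(self, x: float, y: float, elevation: float | None = None) -> int:
        nid = self.graph.number_of_nodes()
        self.graph.add_node(nid, x=float(x), y=float(y), elevation=elevation)
        return nid

    def add_edge(self, u: int, v: int, length: float, geom=None,
                 gradient: float = 0.0, walkable: bool = True) -> int:
        if u == v:
            raise ValueError(f"edge endpoints must be distinct (node {u})")
        for n in (u, v):
            if n not in self.graph:
                raise ValueError(f"edge references missing node {n}")
        if not length > 0:
            raise ValueError(f"edge length must be positive, got {length}")
        if not (math.isfinite(gradient) and gradient >= 0):
            raise ValueError(f"gradient must be finite and >= 0, got {gradient}")
        eid = len(self._edge_order)
        if geom is None:
            geom = [self.node_xy(u), self.node_xy(v)]
        self.graph.add_edge(u, v, length=float(length), gradient=float(gradient),
                            walkable=bool(walkable), eid=eid,
                            geom=[tuple(map(float, c)) for c in geom])
        self._edge_order.append((u, v))
        return eid

    # -- access ------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_xy(self, nid: int) -> tuple[float, float]:
        d = self.graph.nodes[nid]
        return (d["x"], d["y"])

    def node_coords(self) -> np.ndarray:
        """(n_nodes, 2) array of node coordinates, indexed by node id."""
        return np.array([self.node_xy(n) for n in sorted(self.graph.nodes)])

    def edges(self):
        """Edges as (eid, u, v, data), in construction order."""
        for eid, (u, v) in enumerate(self._edge_order):
            yield eid, u, v, self.graph.edges[u, v]

    def total_length(self) -> float:
        return sum(d["length"] for _, _, _, d in self.edges())

    def bounds(self) -> tuple[float, float, float, float]:
        xy = self.node_coords()
        return (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())

    def edge_weight(self, data: dict, metric: str, model: SpeedModel | None = None) -> float:
        if metric == "meters":
            return data["length"]
        if metric == "minutes":
            return traversal_time(data["length"], data["gradient"], model)
        raise ValueError(f"unknown metric {metric!r}; use 'meters' or 'minutes'")


def _looks_like_degrees(coords: np.ndarray) -> bool:
    return bool(np.all(np.abs(coords) <= 360.0))


def _extract_lines(edge_records) -> list[tuple[int, list[tuple[float, float]]]]:
    """Flatten GeoJSON features (or raw coordinate sequences) into
    (record index, coordinate list) polylines."""
    lines = []
    for idx, rec in enumerate(edge_records):
        if isinstance(rec, dict) and "geometry" in rec:
            geom = rec["geometry"]
            gtype = geom["type"]
            if gtype == "LineString":
                parts = [geom["coordinates"]]
            elif gtype == "MultiLineString":
                parts = geom["coordinates"]
            else:
                raise ValueError(
                    f"record {idx}: expected LineString geometry, got {gtype}"
                )
        else:
            parts = [rec]
        for part in parts:
            lines.append((idx, [(float(c[0]), float(c[1])) for c in part]))
    return lines


def build_network(edge_records, snap_tolerance: float = DEFAULT_SNAP_TOLERANCE) -> PedestrianNetwork:
    """Build a :class:`PedestrianNetwork` from line features.

    Each polyline becomes one edge between its endpoints; endpoints closer
    than ``snap_tolerance`` are merged into a single node. Coordinates must
    be projected meters — inputs where every |x| and |y| is <= 360 are
    rejected as likely lon/lat degrees.
    """
    lines = _extract_lines(edge_records)
    if not lines:
        raise ValueError("no line features provided")
    endpoints = []
    for _, coords in lines:
        if len(coords) < 2:
            raise ValueError("polyline with fewer than 2 vertices")
        endpoints.append(coords[0])
        endpoints.append(coords[-1])
    pts = np.array(endpoints, dtype=float)
    if _looks_like_degrees(pts):
        raise ValueError(
            "coordinates look like lon/lat degrees (all |x|,|y| <= 360); "
            "reproject to a metric CRS (e.g. a local UTM or Lambert zone)"
        )

    # merge endpoints within tolerance via union-find over close pairs
    tree = cKDTree(pts)
    parent = list(range(len(pts)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in tree.query_pairs(snap_tolerance):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    net = PedestrianNetwork()
    node_of_root: dict[int, int] = {}
    endpoint_node = []
    for i in range(len(pts)):
        r = find(i)
        if r not in node_of_root:
            node_of_root[r] = net.add_node(pts[r, 0], pts[r, 1])
        endpoint_node.append(node_of_root[r])

    for k, (idx, coords) in enumerate(lines):
        u = endpoint_node[2 * k]
        v = endpoint_node[2 * k + 1]
        length = LineString(coords).length
        if length <= snap_tolerance:
            raise ValueError(f"record {idx}: zero-length edge")
        if u == v:
            raise ValueError(
                f"record {idx}: degenerate loop edge (endpoints merge to one node)"
            )
        if net.graph.has_edge(u, v):
            # parallel records between the same node pair: keep the shorter
            if length < net.graph.edges[u, v]["length"]:
                net.graph.edges[u, v].update(
                    length=float(length),
                    geom=[tuple(map(float, c)) for c in coords],
                )
            continue
        net.add_edge(u, v, length=length, geom=coords)
    return net


def assign_gradients(net: PedestrianNetwork, dtm: ElevationRaster) -> PedestrianNetwork:
    """Sample node elevations from the DTM (bilinear) and set each edge's
    unsigned gradient to |delta elevation| / length x 100. Mutates and
    returns ``net``."""
    for nid in net.graph.nodes:
        x, y = net.node_xy(nid)
        if not dtm.contains(x, y):
            raise ValueError(
                f"node {nid} at ({x:.1f}, {y:.1f}) lies outside the DTM extent"
            )
        net.graph.nodes[nid]["elevation"] = float(dtm.sample(x, y))
    for _, u, v, data in net.edges():
        dz = abs(net.graph.nodes[u]["elevation"] - net.graph.nodes[v]["elevation"])
        data["gradient"] = dz / data["length"] * 100.0
    return net


@dataclass(frozen=True)
class EdgePosition:
    """A point snapped onto the network: edge id, its endpoints, the offset
    along the edge polyline (m) and the snapped coordinate."""

    eid: int
    u: int
    v: int
    offset: float
    point: tuple[float, float]
    snap_distance: float


def snap_point(net: PedestrianNetwork, p, radius: float = DEFAULT_SNAP_RADIUS) -> EdgePosition | None:
    """Nearest on-edge position within ``radius`` of ``p``, or None.

    Ties between equidistant edges break deterministically toward the lowest
    edge id.
    """
    if not radius > 0:
        raise ValueError("snap radius must be positive")
    pt = Point(float(p[0]), float(p[1]))
    best: EdgePosition | None = None
    for eid, u, v, data in net.edges():
        line = LineString(data["geom"])
        d = line.distance(pt)
        if d > radius:
            continue
        if best is None or d < best.snap_distance - 1e-12:
            off = line.project(pt)
            sp = line.interpolate(off)
            best = EdgePosition(eid, u, v, off, (sp.x, sp.y), d)
    return best


@dataclass
class DistanceField:
    """Per-node minimum network distance to the nearest source.

    ``values[node]`` is meters or minutes depending on ``metric``;
    unreachable nodes carry :data:`UNREACHABLE` (infinity)."""

    values: dict[int, float]
    metric: str = "meters"

    def __getitem__(self, node: int) -> float:
        return self.values[node]

    def as_array(self, n_nodes: int) -> np.ndarray:
        out = np.full(n_nodes, UNREACHABLE)
        for n, d in self.values.items():
            out[n] = d
        return out


def distance_field(
    net: PedestrianNetwork,
    sources,
    metric: str = "meters",
    model: SpeedModel | None = None,
    snap_radius: float = DEFAULT_SNAP_RADIUS,
) -> DistanceField:
    """Multi-source shortest-path field over the network's nodes.

    ``sources`` is a sequence of (x, y) points; each is snapped to the
    nearest edge within ``snap_radius`` and, when it falls mid-edge, splits
    that edge's cost proportionally. ``metric`` selects meters or walking
    minutes (via :func:`traversal_time`). Raises if no source snaps.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("empty source set")
    snapped = [snap_point(net, p, snap_radius) for p in sources]
    snapped = [s for s in snapped if s is not None]
    if not snapped:
        raise ValueError(
            f"no source lies within {snap_radius} m of the network"
        )

    g = nx.Graph()
    for _, u, v, data in net.edges():
        g.add_edge(u, v, w=net.edge_weight(data, metric, model))
    g.add_nodes_from(net.graph.nodes)

    virtual = []
    for i, s in enumerate(snapped):
        data = net.graph.edges[s.u, s.v]
        w_edge = net.edge_weight(data, metric, model)
        frac = s.offset / data["length"]
        vs = ("src", i)
        # mid-edge source splits the edge cost proportionally
        wu = w_edge * frac
        wv = w_edge * (1.0 - frac)
        g.add_edge(vs, s.u, w=min(wu, g.edges[vs, s.u]["w"]) if g.has_edge(vs, s.u) else wu)
        g.add_edge(vs, s.v, w=min(wv, g.edges[vs, s.v]["w"]) if g.has_edge(vs, s.v) else wv)
        virtual.append(vs)

    dist = nx.multi_source_dijkstra_path_length(g, set(virtual), weight="w")
    values = {}
    for n in net.graph.nodes:
        d = dist.get(n, UNREACHABLE)
        values[n] = 0.0 if d < 1e-12 else d
    return DistanceField(values=values, metric=metric)


def field_to_csv(fieldobj: DistanceField, net: PedestrianNetwork, path) -> None:
    """Write a distance field as CSV: node_id, x, y, distance."""
    unit = "distance_m" if fieldobj.metric == "meters" else "distance_min"
    with open(path, "w") as fh:
        fh.write(f"node_id,x,y,{unit}\n")
        for n in sorted(fieldobj.values):
            x, y = net.node_xy(n)
            d = fieldobj.values[n]
            dtxt = "unreachable" if math.isinf(d) else f"{d:.3f}"
            fh.write(f"{n},{x:.3f},{y:.3f},{dtxt}\n")


def field_to_features(fieldobj: DistanceField, net: PedestrianNetwork) -> list[dict]:
    """Distance field as point GeoJSON features."""
    from .geojson import point_feature

    feats = []
    for n in sorted(fieldobj.values):
        x, y = net.node_xy(n)
        d = fieldobj.values[n]
        feats.append(point_feature(
            x, y, node_id=n,
            distance=None if math.isinf(d) else round(d, 3),
            metric=fieldobj.metric,
        ))
    return feats
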