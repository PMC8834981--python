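"""Synthetic neighborhoods: street network, amenities, and terrain.

Generates fully self-contained inputs with the statistical structure the
accessibility model assumes: a connected walkable graph over a rectangular
extent, benches and categorized facilities placed along the streets, and a
smooth elevation field. Two presets bracket the contrast between urban
forms the model is designed to discriminate:

* ``b_like`` — a dense orthogonal street grid on flat terrain with a rich
  amenity inventory (169 benches; 45 facilities across the five groups):
  a compact, walkable town center.
* ``a_like`` — sparse suburban loops on a ~10% ramp with a thin inventory
  (53 benches; 27 facilities): a hilly residential periphery.

All randomness flows from one seeded generator per call; identical configs
and seeds produce byte-identical GeoJSON and ASCII-grid outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import ndimage

from .geojson import line_feature, point_feature, write_features
from .inventory import FACILITY_GROUPS, BENCH_KINDS, SiteInventory, load_inventory
from .network import PedestrianNetwork, build_network
from .terrain import ElevationRaster, write_ascii_grid

__all__ = ["NeighborhoodConfig", "SyntheticNeighborhood", "generate_neighborhood", "presets"]


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Parameters of one synthetic neighborhood.

    ``terrain`` is ``("flat",)``, ``("ramp", slope_percent)`` or
    ``("smooth-noise", amplitude_m, length_scale_m)``; ``extent`` is the
    (width, height) of the area in meters and ``spacing`` the street
    spacing of the underlying grid.
    """

    name: str = "synthetic"
    extent: tuple[float, float] = (800.0, 800.0)
    pattern: str = "grid"  # "grid" | "suburban-loops"
    spacing: float = 100.0
    n_benches: int = 50
    facility_counts: dict[str, int] = field(
        default_factory=lambda: {g: 2 for g in FACILITY_GROUPS}
    )
    terrain: tuple = ("flat",)
    dtm_cellsize: float = 25.0
    base_elevation: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("grid", "suburban-loops"):
            raise ValueError(f"unknown street pattern {self.pattern!r}")
        if not self.spacing > 0:
            raise ValueError("street spacing must be positive")
        if self.n_benches < 0 or any(c < 0 for c in self.facility_counts.values()):
            raise ValueError("amenity counts must be non-negative")
        if self.terrain[0] == "ramp" and self.terrain[1] < 0:
            raise ValueError("ramp slope must be non-negative")
        w, h = self.extent
        if w < self.spacing or h < self.spacing:
            raise ValueError(
                f"extent {self.extent} too small for street spacing {self.spacing}"
            )


@dataclass
class SyntheticNeighborhood:
    """One generated neighborhood, as the GeoJSON/raster artifacts the
    pipeline reads plus ready-made in-memory objects."""

    config: NeighborhoodConfig
    network_features: list[dict]
    bench_features: list[dict]
    facility_features: list[dict]
    dtm: ElevationRaster

    def network(self) -> PedestrianNetwork:
        return build_network(self.network_features)

    def inventory(self) -> SiteInventory:
        return load_inventory(self.facility_features, self.bench_features)

    def write(self, outdir) -> dict[str, str]:
        """Write network/benches/facilities GeoJSON and the DTM .asc;
        byte-identical across runs with the same config."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "network": os.path.join(outdir, "network.geojson"),
            "benches": os.path.join(outdir, "benches.geojson"),
            "facilities": os.path.join(outdir, "facilities.geojson"),
            "dtm": os.path.join(outdir, "dtm.asc"),
        }
        write_features(self.network_features, paths["network"])
        write_features(self.bench_features, paths["benches"])
        write_features(self.facility_features, paths["facilities"])
        write_ascii_grid(self.dtm, paths["dtm"], fmt="%.3f")
        return paths


# offset so synthetic coordinates never look like lon/lat degrees
_X0 = 10000.0
_Y0 = 20000.0


def _street_edges(cfg: NeighborhoodConfig, rng: np.random.Generator):
    """Node grid + edge list for the street pattern, in abstract (i, j)."""
    w, h = cfg.extent
    nx_ = int(w // cfg.spacing) + 1
    ny_ = int(h // cfg.spacing) + 1
    g = nx.Graph()
    for i in range(nx_):
        for j in range(ny_):
            g.add_node((i, j))
    for i in range(nx_):
        for j in range(ny_):
            if i + 1 < nx_:
                g.add_edge((i, j), (i + 1, j))
            if j + 1 < ny_:
                g.add_edge((i, j), (i, j + 1))
    if cfg.pattern == "suburban-loops":
        # thin the grid into loops: drop edges at random while the graph
        # stays connected, keeping roughly 60% of street length
        edges = sorted(g.edges)
        rng.shuffle(edges)
        target = int(0.4 * len(edges))
        removed = 0
        for e in edges:
            if removed >= target:
                break
            g.remove_edge(*e)
            if nx.is_connected(g):
                removed += 1
            else:
                g.add_edge(*e)
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return g


def _terrain_value(cfg: NeighborhoodConfig, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    kind = cfg.terrain[0]
    if kind == "flat":
        return np.full_like(X, cfg.base_elevation)
    if kind == "ramp":
        slope = cfg.terrain[1]
        return cfg.base_elevation + slope / 100.0 * (X - X.min())
    if kind == "smooth-noise":
        amplitude, length_scale = cfg.terrain[1], cfg.terrain[2]
        noise = rng.standard_normal(X.shape)
        sigma = max(length_scale / cfg.dtm_cellsize, 1e-6)
        smooth = ndimage.gaussian_filter(noise, sigma, mode="nearest")
        peak = np.abs(smooth).max()
        if peak > 0:
            smooth = smooth / peak * amplitude
        return cfg.base_elevation + smooth
    raise ValueError(f"unknown terrain kind {kind!r}")


def _place_along_network(net: PedestrianNetwork, n: int, rng: np.random.Generator,
                         lateral: float = 5.0) -> list[tuple[float, float]]:
    """Sample n points uniformly along total street length, with a small
    perpendicular offset so amenities sit beside, not on, the centreline."""
    edges = list(net.edges())
    lengths = np.array([d["length"] for _, _, _, d in edges])
    cum = np.cumsum(lengths)
    total = cum[-1]
    pts = []
    for _ in range(n):
        s = rng.uniform(0.0, total)
        k = int(np.searchsorted(cum, s))
        k = min(k, len(edges) - 1)
        _, u, v, d = edges[k]
        t = (s - (cum[k] - lengths[k])) / lengths[k]
        (x1, y1), (x2, y2) = net.node_xy(u), net.node_xy(v)
        x = x1 + t * (x2 - x1)
        y = y1 + t * (y2 - y1)
        # unit normal to the edge
        ex, ey = (x2 - x1) / lengths[k], (y2 - y1) / lengths[k]
        off = rng.uniform(-lateral, lateral)
        pts.append((x - ey * off, y + ex * off))
    return pts


def generate_neighborhood(cfg: NeighborhoodConfig) -> SyntheticNeighborhood:
    """Generate one synthetic neighborhood from a config.

    The network is connected and covers the extent; benches and facilities
    lie within the default snap radius of an edge; the DTM covers the
    network with a margin. Identical configs (seed included) give
    byte-identical artifacts.
    """
    rng = np.random.default_rng(cfg.seed)
    streets = _street_edges(cfg, rng)

    def xy(ij):
        return (_X0 + ij[0] * cfg.spacing, _Y0 + ij[1] * cfg.spacing)

    network_features = []
    for a, b in sorted(streets.edges):
        network_features.append(line_feature([xy(a), xy(b)], zone=cfg.name))
    net = build_network(network_features)

    bench_pts = _place_along_network(net, cfg.n_benches, rng)
    bench_features = []
    for i, (x, y) in enumerate(bench_pts):
        kind = BENCH_KINDS[int(rng.integers(len(BENCH_KINDS)))]
        bench_features.append(point_feature(
            x, y, id=f"{cfg.name}-bench-{i}", kind=kind, zone=cfg.name))

    facility_features = []
    i = 0
    for group in FACILITY_GROUPS:
        n = cfg.facility_counts.get(group, 0)
        for x, y in _place_along_network(net, n, rng):
            facility_features.append(point_feature(
                x, y, id=f"{cfg.name}-fac-{i}", group=group, zone=cfg.name))
            i += 1

    # DTM: cover the network bounds plus a margin of one street spacing
    xmin, ymin, xmax, ymax = net.bounds()
    m = cfg.spacing
    cs = cfg.dtm_cellsize
    n_cols = int(math.ceil((xmax - xmin + 2 * m) / cs)) + 1
    n_rows = int(math.ceil((ymax - ymin + 2 * m) / cs)) + 1
    origin_x = xmin - m
    origin_y = ymax + m
    xs = origin_x + (np.arange(n_cols) + 0.5) * cs
    ys = origin_y - (np.arange(n_rows) + 0.5) * cs
    X, _ = np.meshgrid(xs, ys)
    z = _terrain_value(cfg, X, rng)
    dtm = ElevationRaster(origin_x, origin_y, cs, z)

    return SyntheticNeighborhood(cfg, network_features, bench_features,
                                 facility_features, dtm)


def presets() -> dict[str, NeighborhoodConfig]:
    """The two contrasting neighborhood presets.

    ``a_like``: sparse suburban loops, sloped (10% ramp), 53 benches and 27
    facilities. ``b_like``: dense flat grid, 169 benches and 45 facilities.
    The facility group counts follow the two surveyed inventories.
    """
    a_counts = {
        "health_services": 2,
        "municipal": 3,
        "social_cultural": 8,
        "shopping": 10,
        "schools_childcare": 4,
    }  # totals 27
    b_counts = {
        "health_services": 7,
        "municipal": 7,
        "social_cultural": 6,
        "shopping": 20,
        "schools_childcare": 5,
    }  # totals 45
    return {
        "a_like": NeighborhoodConfig(
            name="A", extent=(800.0, 800.0), pattern="suburban-loops",
            spacing=200.0, n_benches=53, facility_counts=a_counts,
            terrain=("ramp", 10.0), seed=0,
        ),
        "b_like": NeighborhoodConfig(
            name="B", extent=(800.0, 800.0), pattern="grid",
            spacing=100.0, n_benches=169, facility_counts=b_counts,
            terrain=("flat",), seed=0,
        ),
    }
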