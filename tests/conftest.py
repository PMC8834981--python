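"""Shared fixtures: small programmatic towns, rasters and inventories."""

import numpy as np
import pytest

from pedaccess import (
    AnalysisGrid,
    ElevationRaster,
    PedestrianNetwork,
    build_network,
)
from pedaccess.geojson import line_feature, point_feature

# offset keeping synthetic coordinates clear of the lon/lat degree heuristic
X0, Y0 = 10000.0, 20000.0


def grid_town_features(n: int = 5, spacing: float = 100.0):
    """Line features for an n x n orthogonal street grid."""
    feats = []
    for i in range(n):
        for j in range(n):
            x, y = X0 + i * spacing, Y0 + j * spacing
            if i + 1 < n:
                feats.append(line_feature([(x, y), (x + spacing, y)]))
            if j + 1 < n:
                feats.append(line_feature([(x, y), (x, y + spacing)]))
    return feats


def flat_dtm(bounds, cellsize=25.0, elevation=100.0, margin=100.0):
    xmin, ymin, xmax, ymax = bounds
    n_cols = int((xmax - xmin + 2 * margin) / cellsize) + 1
    n_rows = int((ymax - ymin + 2 * margin) / cellsize) + 1
    return ElevationRaster(
        xmin - margin, ymax + margin, cellsize,
        np.full((n_rows, n_cols), elevation),
    )


def ramp_dtm(bounds, grade_pct, cellsize=25.0, margin=100.0):
    """Plane rising grade_pct% along +x."""
    xmin, ymin, xmax, ymax = bounds
    n_cols = int((xmax - xmin + 2 * margin) / cellsize) + 1
    n_rows = int((ymax - ymin + 2 * margin) / cellsize) + 1
    ox, oy = xmin - margin, ymax + margin
    xs = ox + (np.arange(n_cols) + 0.5) * cellsize
    X = np.tile(xs, (n_rows, 1))
    return ElevationRaster(ox, oy, cellsize, 100.0 + grade_pct / 100.0 * (X - xs[0]))


def random_network(rng, n_nodes=40, extra_edges=20, extent=1000.0) -> PedestrianNetwork:
    """Connected random geometric network: spanning tree + extra chords."""
    net = PedestrianNetwork()
    pts = rng.uniform(0, extent, size=(n_nodes, 2)) + [X0, Y0]
    for x, y in pts:
        net.add_node(x, y)
    order = rng.permutation(n_nodes)
    for k in range(1, n_nodes):
        u = int(order[k])
        v = int(order[int(rng.integers(0, k))])
        net.add_edge(u, v, length=float(np.hypot(*(pts[u] - pts[v]))) + 1e-9)
    added = 0
    while added < extra_edges:
        u, v = (int(i) for i in rng.integers(0, n_nodes, 2))
        if u == v or net.graph.has_edge(u, v):
            continue
        net.add_edge(u, v, length=float(np.hypot(*(pts[u] - pts[v]))) + 1e-9)
        added += 1
    return net


@pytest.fixture
def town5():
    """5x5 grid town, 100 m spacing."""
    return build_network(grid_town_features(5, 100.0))


@pytest.fixture
def town5_grid(town5):
    xmin, ymin, xmax, ymax = town5.bounds()
    return AnalysisGrid.from_bounds(xmin, ymin, xmax, ymax, cellsize=20.0)


def bench_point(x, y, i=0, zone=""):
    return point_feature(x, y, id=f"b{i}", kind="formal", zone=zone)


def facility_point(x, y, group, i=0, zone=""):
    return point_feature(x, y, id=f"f{i}", group=group, zone=zone)
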