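"""Weighted-overlay accessibility model.

Every input variable — network distance to the nearest bench, network
distance to the nearest service/facility (optionally split into health
services vs the rest), and percent slope — is rasterized onto a common
analysis grid (5 m cells by default), reclassified onto a shared five-level
ordinal scale (1 = Very Low ... 5 = Very High), and combined cell-wise as a
weighted linear combination

    PA = sum_i w_i * r_i,   sum_i w_i = 1,

where ``r_i`` is a variable's level layer and ``w_i`` its weight under a
named older-adult profile. The continuous potential-accessibility surface PA
is quantized back to the five classes for mapping and per-class area
summaries.

Band conventions: distance bands are half-open ``[lo, hi)`` in meters, so a
value exactly on a printed boundary (100 m) takes the better-ranked upper
band's neighbour as printed; slope bands are upper-closed ``(lo, hi]`` in
percent, matching two-decimal printed edges (3.01–5.00 => (3, 5]). Values
beyond the last band — and cells no source can reach — fall to level 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .inventory import SiteInventory, select_sources
from .network import (
    DEFAULT_SNAP_RADIUS,
    DistanceField,
    PedestrianNetwork,
    distance_field,
)
from .terrain import ElevationRaster, Raster, slope_percent

__all__ = [
    "CLASS_LABELS",
    "AnalysisGrid",
    "ReclassTable",
    "LevelLayer",
    "ProfileWeights",
    "AccessibilitySurface",
    "builtin_profiles",
    "builtin_reclass_tables",
    "distance_raster",
    "reclassify",
    "weighted_sum",
    "quantize",
    "area_summary",
    "run_model",
    "load_model_config",
]

CLASS_LABELS = {1: "Very Low", 2: "Low", 3: "Moderate", 4: "High", 5: "Very High"}

#: Cells farther than this from any network node are treated as unreached (m).
DEFAULT_OFF_NETWORK_RADIUS = 100.0

UNREACHED = math.inf


@dataclass
class AnalysisGrid:
    """The common raster grid all layers are computed on.

    ``origin_x``/``origin_y`` is the top-left corner; ``mask`` (optional)
    flags the cells inside the study zone."""

    origin_x: float
    origin_y: float
    n_rows: int
    n_cols: int
    cellsize: float = 5.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.cellsize > 0:
            raise ValueError("cell size must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_rows, self.n_cols):
                raise ValueError("mask shape must match the grid")

    @classmethod
    def from_bounds(cls, xmin, ymin, xmax, ymax, cellsize: float = 5.0) -> "AnalysisGrid":
        n_cols = max(1, int(math.ceil((xmax - xmin) / cellsize)))
        n_rows = max(1, int(math.ceil((ymax - ymin) / cellsize)))
        return cls(xmin, ymin + n_rows * cellsize, n_rows, n_cols, cellsize)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cellsize,
            self.origin_x + self.n_cols * self.cellsize,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cellsize
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def valid(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.mask

    def to_raster(self, values: np.ndarray, nodata: float = -9999.0) -> Raster:
        """Wrap an array on this grid as a raster (masked cells -> nodata)."""
        out = np.array(values, dtype=float)
        out[~self.valid()] = nodata
        out[~np.isfinite(out)] = nodata
        return Raster(self.origin_x, self.origin_y, self.cellsize, out, nodata)


@dataclass(frozen=True)
class Band:
    lo: float
    hi: float
    level: int


@dataclass
class ReclassTable:
    """Ordered bands mapping a variable's values to levels 5 (best) .. 1.

    ``closed`` picks the boundary convention: ``"left"`` for half-open
    ``[lo, hi)`` bands (distances), ``"right"`` for ``(lo, hi]`` (slope).
    Values beyond the last band take level 1.
    """

    variable: str
    bands: list[Band]
    units: str = "m"
    closed: str = "left"

    def __post_init__(self) -> None:
        self.bands = [b if isinstance(b, Band) else Band(*b) for b in self.bands]
        if self.closed not in ("left", "right"):
            raise ValueError("closed must be 'left' or 'right'")
        if not self.bands:
            raise ValueError("empty reclass table")
        if self.bands[0].lo != 0:
            raise ValueError("bands must start at 0")
        levels = [b.level for b in self.bands]
        if levels != sorted(levels, reverse=True) or len(set(levels)) != len(levels):
            raise ValueError("band levels must be strictly decreasing")
        if any(not 1 <= l <= 5 for l in levels):
            raise ValueError("levels must lie in 1..5")
        for a, b in zip(self.bands, self.bands[1:]):
            if not math.isclose(a.hi, b.lo):
                raise ValueError(
                    f"bands must be contiguous: {a.hi} != {b.lo} in {self.variable}"
                )
            if not a.hi > a.lo:
                raise ValueError("band upper bound must exceed lower bound")

    def lookup(self, values: np.ndarray) -> np.ndarray:
        """Vectorized band lookup; inf (unreached) and beyond-last-band
        values take the worst level; NaN (nodata) propagates as 0."""
        v = np.asarray(values, dtype=float)
        finite = np.isfinite(v)
        if np.any(v[finite] < 0):
            raise ValueError(f"negative {self.variable} value in reclassify")
        uppers = np.array([b.hi for b in self.bands[:-1]])
        side = "right" if self.closed == "left" else "left"
        idx = np.searchsorted(uppers, np.where(finite, v, 0.0), side=side)
        idx = np.minimum(idx, len(self.bands) - 1)
        levels = np.array([b.level for b in self.bands])
        out = levels[idx].astype(float)
        # beyond the final band (and unreachable cells): worst level
        last_hi = self.bands[-1].hi
        beyond = ~np.isnan(v) & (
            (v > last_hi) if self.closed == "right" else (v >= last_hi)
        )
        out[beyond] = 1.0
        out[np.isnan(v)] = np.nan
        return out


@dataclass
class LevelLayer:
    """A variable reclassified onto the 1..5 ordinal scale on a grid;
    NaN marks cells outside the study mask."""

    grid: AnalysisGrid
    values: np.ndarray
    variable: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("layer shape must match its grid")
        valid = self.values[~np.isnan(self.values)]
        if valid.size and (valid.min() < 1 or valid.max() > 5):
            raise ValueError("levels must lie in 1..5")


@dataclass
class ProfileWeights:
    """A named weight vector over the model variables.

    ``split_services`` is True only for profiles that separate health
    services from the other facility groups (the chronic-disease profile);
    weights must be non-negative and sum to 1.
    """

    profile: str
    weights: dict[str, float]
    split_services: bool = False

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        need = {"benches", "slope"}
        need |= {"health_services", "other_services"} if self.split_services else {"all_services"}
        if set(self.weights) != need:
            raise ValueError(
                f"profile {self.profile!r} must weight exactly {sorted(need)}, "
                f"got {sorted(self.weights)}"
            )

    @property
    def service_variables(self) -> tuple[str, ...]:
        if self.split_services:
            return ("health_services", "other_services")
        return ("all_services",)


@dataclass
class AccessibilitySurface:
    """The model output: continuous PA per cell plus its five-class map."""

    grid: AnalysisGrid
    pa: np.ndarray
    classes: np.ndarray
    profile: str

    def pa_raster(self) -> Raster:
        return self.grid.to_raster(self.pa)

    def class_raster(self) -> Raster:
        return self.grid.to_raster(self.classes)


def builtin_profiles() -> dict[str, ProfileWeights]:
    """The three built-in older-adult profiles.

    * ``healthy`` — services and benches dominate (45% each), slope 10%.
    * ``chronic_disease`` — health services 40%, other services 10%,
      benches 30%, slope 20%; the only profile that splits services.
    * ``reduced_mobility`` — slope dominates (40%), benches and services 30%.
    """
    return {
        "healthy": ProfileWeights(
            "healthy", {"benches": 0.45, "all_services": 0.45, "slope": 0.10}
        ),
        "chronic_disease": ProfileWeights(
            "chronic_disease",
            {"benches": 0.30, "health_services": 0.40,
             "other_services": 0.10, "slope": 0.20},
            split_services=True,
        ),
        "reduced_mobility": ProfileWeights(
            "reduced_mobility", {"benches": 0.30, "all_services": 0.30, "slope": 0.40}
        ),
    }


def builtin_reclass_tables() -> dict[str, ReclassTable]:
    """Default band tables: bench distance, service distance (m, half-open
    bands) and percent slope (upper-closed bands)."""
    service_bands = [(0, 100, 5), (100, 300, 4), (300, 600, 3), (600, 800, 2), (800, 1000, 1)]
    return {
        "benches": ReclassTable(
            "benches",
            [(0, 100, 5), (100, 300, 4), (300, 500, 3), (500, 700, 2), (700, 1000, 1)],
            units="m", closed="left",
        ),
        "all_services": ReclassTable("all_services", list(service_bands), units="m", closed="left"),
        "health_services": ReclassTable("health_services", list(service_bands), units="m", closed="left"),
        "other_services": ReclassTable("other_services", list(service_bands), units="m", closed="left"),
        "slope": ReclassTable(
            "slope",
            [(0, 3, 5), (3, 5, 4), (5, 8, 3), (8, 12, 2), (12, 100, 1)],
            units="%", closed="right",
        ),
    }


def distance_raster(
    fieldobj: DistanceField,
    net: PedestrianNetwork,
    grid: AnalysisGrid,
    off_network_radius: float = DEFAULT_OFF_NETWORK_RADIUS,
) -> np.ndarray:
    """Rasterize a node distance field onto the analysis grid.

    Each cell takes the field value at its nearest network node (within
    ``off_network_radius``) plus the straight-line distance to that node;
    cells with no node in range are unreached (inf). Masked cells are NaN.
    """
    gxmin, gymin, gxmax, gymax = grid.bounds
    nxmin, nymin, nxmax, nymax = net.bounds()
    if gxmax < nxmin or nxmax < gxmin or gymax < nymin or nymax < gymin:
        raise ValueError(
            "grid and network bounding boxes are disjoint — likely a CRS mismatch"
        )
    coords = net.node_coords()
    tree = cKDTree(coords)
    X, Y = grid.cell_centers()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    d, i = tree.query(pts, distance_upper_bound=off_network_radius)
    fvals = fieldobj.as_array(len(coords))
    out = np.full(len(pts), UNREACHED)
    hit = np.isfinite(d)
    out[hit] = fvals[i[hit]] + d[hit]
    out = out.reshape(grid.shape)
    out[~grid.valid()] = np.nan
    return out


def reclassify(values: np.ndarray, table: ReclassTable, grid: AnalysisGrid) -> LevelLayer:
    """Reclassify a value raster onto the 1..5 scale using ``table``."""
    return LevelLayer(grid, table.lookup(values), table.variable)


def weighted_sum(layers: dict[str, LevelLayer], weights: ProfileWeights) -> AccessibilitySurface:
    """Cell-wise weighted linear combination PA = sum w_i r_i.

    Layer names must match the profile's weight keys exactly and all layers
    must share one grid."""
    missing = set(weights.weights) - set(layers)
    extra = set(layers) - set(weights.weights)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing layer(s): {sorted(missing)}")
        if extra:
            parts.append(f"unexpected layer(s): {sorted(extra)}")
        raise ValueError("; ".join(parts))
    headers = {
        (l.grid.origin_x, l.grid.origin_y, l.grid.n_rows, l.grid.n_cols, l.grid.cellsize)
        for l in layers.values()
    }
    if len(headers) != 1:
        raise ValueError("all layers must share the same grid header")
    grid = next(iter(layers.values())).grid
    pa = np.zeros(grid.shape)
    for name, w in weights.weights.items():
        pa = pa + w * layers[name].values
    classes = quantize(pa)
    return AccessibilitySurface(grid, pa, classes, weights.profile)


def quantize(pa: np.ndarray) -> np.ndarray:
    """Quantize continuous PA in [1, 5] to the nearest class, ties (x.5)
    rounding up; NaN (outside the mask) propagates."""
    v = np.asarray(pa, dtype=float)
    finite = v[~np.isnan(v)]
    if finite.size and (finite.min() < 1 - 1e-9 or finite.max() > 5 + 1e-9):
        raise ValueError(
            f"PA values must lie in [1, 5], got range "
            f"[{finite.min():.3f}, {finite.max():.3f}]"
        )
    out = np.floor(v + 0.5)
    return np.clip(out, 1.0, 5.0)  # NaN propagates


def area_summary(classes: np.ndarray, grid: AnalysisGrid) -> dict[int, float]:
    """Percent of the (unmasked) study area in each of the five classes.

    All five classes are reported, zeros included; percentages are exact
    (rounding is left to presentation)."""
    v = np.asarray(classes, dtype=float)
    valid = grid.valid() & ~np.isnan(v)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("area summary over a fully masked grid")
    out = {}
    for c in range(1, 6):
        out[c] = 100.0 * float(np.sum(v[valid] == c)) / n
    return out


def summary_to_csv(summary: dict[int, float], profile: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("profile,class,label,percent\n")
        for c in range(1, 6):
            fh.write(f"{profile},{c},{CLASS_LABELS[c]},{summary[c]:.4f}\n")


def run_model(
    net: PedestrianNetwork,
    dtm: ElevationRaster,
    inv: SiteInventory,
    grid: AnalysisGrid,
    profile: ProfileWeights | str = "healthy",
    reclass_tables: dict[str, ReclassTable] | None = None,
    off_network_radius: float = DEFAULT_OFF_NETWORK_RADIUS,
    snap_radius: float = DEFAULT_SNAP_RADIUS,
) -> tuple[AccessibilitySurface, dict[int, float]]:
    """Run the full pipeline for one profile.

    Stages: multi-source network distance fields for benches and for the
    service variable(s) the profile demands, rasterized to the grid and
    reclassified; percent slope from the DTM, bilinearly resampled onto the
    grid and reclassified; then the weighted sum, quantization, and the
    per-class area summary. Deterministic given its inputs. Distance layers
    are banded in meters (the band tables are metric).
    """
    if isinstance(profile, str):
        profiles = builtin_profiles()
        if profile not in profiles:
            raise ValueError(
                f"unknown profile {profile!r}; builtin profiles: "
                f"{', '.join(sorted(profiles))}"
            )
        profile = profiles[profile]
    tables = reclass_tables or builtin_reclass_tables()

    layers: dict[str, LevelLayer] = {}
    for var in ("benches",) + profile.service_variables:
        try:
            srcs = select_sources(inv, var)
            fld = distance_field(net, srcs, metric="meters", snap_radius=snap_radius)
            vals = distance_raster(fld, net, grid, off_network_radius)
            layers[var] = reclassify(vals, tables[var], grid)
        except ValueError as e:
            raise ValueError(f"[{var}] {e}") from e

    try:
        slope = slope_percent(dtm)
        X, Y = grid.cell_centers()
        svals = np.asarray(slope.sample(X, Y), dtype=float)
        svals[~grid.valid()] = np.nan
        layers["slope"] = reclassify(svals, tables["slope"], grid)
    except ValueError as e:
        raise ValueError(f"[slope] {e}") from e

    try:
        surface = weighted_sum(layers, profile)
        summary = area_summary(surface.classes, grid)
    except ValueError as e:
        raise ValueError(f"[overlay] {e}") from e
    return surface, summary


def load_model_config(path) -> tuple[dict[str, ProfileWeights], dict[str, ReclassTable]]:
    """Load profile weights and band tables from a YAML config.

    Schema::

        profiles:
          my_profile: {benches: 0.4, all_services: 0.4, slope: 0.2}
        variables:
          benches: {units: m, closed: left, bands: [[0, 100, 5], ...]}

    A profile weighting ``health_services``/``other_services`` instead of
    ``all_services`` is treated as split. Omitted sections fall back to the
    built-ins. Validation errors name the offending profile or variable.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    profiles = builtin_profiles()
    for name, w in (cfg.get("profiles") or {}).items():
        w = {k: float(v) for k, v in w.items()}
        split = "health_services" in w or "other_services" in w
        profiles[name] = ProfileWeights(name, w, split_services=split)
    tables = builtin_reclass_tables()
    for name, vdef in (cfg.get("variables") or {}).items():
        tables[name] = ReclassTable(
            name,
            [tuple(b) for b in vdef["bands"]],
            units=vdef.get("units", "m"),
            closed=vdef.get("closed", "left"),
        )
    return profiles, tables
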