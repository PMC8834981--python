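"""Point amenities: benches and the five facility groups.

Facilities are classified into five fixed groups (health services, municipal
services and amenities, social and cultural facilities, shopping, schools and
childcare); benches keep their surveyed kind (formal street bench, bus-stop
bench, informal seating such as a low wall) as metadata, but every kind counts
as a resting opportunity — a bus-stop bench serves equally well as a relay
bench during a walk, so all three enter the proximity model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "FACILITY_GROUPS",
    "BENCH_KINDS",
    "FacilitySite",
    "BenchSite",
    "SiteInventory",
    "load_inventory",
    "count_by_group",
    "select_sources",
]

FACILITY_GROUPS = (
    "health_services",
    "municipal",
    "social_cultural",
    "shopping",
    "schools_childcare",
)

BENCH_KINDS = ("formal", "bus_stop", "informal")

#: Source-selection variables understood by :func:`select_sources`.
SOURCE_VARIABLES = ("benches", "health_services", "other_services", "all_services")


@dataclass(frozen=True)
class FacilitySite:
    id: str
    x: float
    y: float
    group: str
    subtype: str = ""
    zone: str = ""

    def __post_init__(self) -> None:
        if self.group not in FACILITY_GROUPS:
            raise ValueError(
                f"unknown facility group {self.group!r}; "
                f"expected one of {', '.join(FACILITY_GROUPS)}"
            )


@dataclass(frozen=True)
class BenchSite:
    id: str
    x: float
    y: float
    kind: str = "formal"
    zone: str = ""

    def __post_init__(self) -> None:
        if self.kind not in BENCH_KINDS:
            raise ValueError(
                f"unknown bench kind {self.kind!r}; "
                f"expected one of {', '.join(BENCH_KINDS)}"
            )


@dataclass
class SiteInventory:
    facilities: list[FacilitySite] = field(default_factory=list)
    benches: list[BenchSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, items in (("facility", self.facilities), ("bench", self.benches)):
            ids = [s.id for s in items]
            if len(ids) != len(set(ids)):
                dup = next(i for i, c in Counter(ids).items() if c > 1)
                raise ValueError(f"duplicate {name} id {dup!r}")

    @property
    def zones(self) -> set[str]:
        return {s.zone for s in self.facilities} | {s.zone for s in self.benches}


def _point_xy(feature: dict, idx: int) -> tuple[float, float]:
    geom = feature.get("geometry") or {}
    if geom.get("type") != "Point":
        raise ValueError(
            f"feature {idx}: expected Point geometry, got {geom.get('type')!r}"
        )
    x, y = geom["coordinates"][:2]
    return float(x), float(y)


def load_inventory(facility_features=(), bench_features=()) -> SiteInventory:
    """Build a validated :class:`SiteInventory` from point GeoJSON features.

    Facility features need a ``group`` property (one of the five groups);
    bench features may carry ``kind`` (default ``formal``). Unknown
    categories are rejected naming the offending value. Empty inputs yield a
    valid empty inventory.
    """
    facilities = []
    for i, f in enumerate(facility_features):
        x, y = _point_xy(f, i)
        props = f.get("properties") or {}
        facilities.append(FacilitySite(
            id=str(props.get("id", f"fac-{i}")),
            x=x, y=y,
            group=props.get("group", ""),
            subtype=str(props.get("subtype", "")),
            zone=str(props.get("zone", "")),
        ))
    benches = []
    for i, f in enumerate(bench_features):
        x, y = _point_xy(f, i)
        props = f.get("properties") or {}
        benches.append(BenchSite(
            id=str(props.get("id", f"bench-{i}")),
            x=x, y=y,
            kind=props.get("kind", "formal"),
            zone=str(props.get("zone", "")),
        ))
    return SiteInventory(facilities=facilities, benches=benches)


def count_by_group(inv: SiteInventory, zone: str | None = None) -> dict[str, int]:
    """Facility tallies per group plus ``total`` (and ``benches``) for a zone.

    ``zone=None`` counts the whole inventory; an unknown zone label raises.
    """
    if zone is not None and zone not in inv.zones:
        raise ValueError(f"unknown zone {zone!r}; known zones: {sorted(inv.zones)}")
    fac = [s for s in inv.facilities if zone is None or s.zone == zone]
    ben = [s for s in inv.benches if zone is None or s.zone == zone]
    counts = {g: 0 for g in FACILITY_GROUPS}
    for s in fac:
        counts[s.group] += 1
    counts["total"] = len(fac)
    counts["benches"] = len(ben)
    return counts


def select_sources(inv: SiteInventory, variable: str) -> list[tuple[float, float]]:
    """Source coordinates for a proximity variable.

    ``benches`` selects every bench regardless of kind; ``health_services``
    the health group only; ``other_services`` the remaining four groups;
    ``all_services`` all five. An empty selection raises — a proximity layer
    with no sources is meaningless.
    """
    if variable == "benches":
        pts = [(s.x, s.y) for s in inv.benches]
    elif variable == "health_services":
        pts = [(s.x, s.y) for s in inv.facilities if s.group == "health_services"]
    elif variable == "other_services":
        pts = [(s.x, s.y) for s in inv.facilities if s.group != "health_services"]
    elif variable == "all_services":
        pts = [(s.x, s.y) for s in inv.facilities]
    else:
        raise ValueError(
            f"unknown variable {variable!r}; expected one of {', '.join(SOURCE_VARIABLES)}"
        )
    if not pts:
        raise ValueError(f"no source sites for variable {variable!r}")
    return pts


def counts_to_csv(counts_by_zone: dict[str, dict[str, int]], path) -> None:
    """Write per-zone group counts as CSV (group rows, one column per zone)."""
    zones = list(counts_by_zone)
    rows = list(FACILITY_GROUPS) + ["total", "benches"]
    with open(path, "w") as fh:
        fh.write("group," + ",".join(zones) + "\n")
        for r in rows:
            fh.write(r + "," + ",".join(str(counts_by_zone[z][r]) for z in zones) + "\n")
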