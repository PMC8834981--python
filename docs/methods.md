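# Methods

## Model

The package computes a *potential accessibility* (PA) surface for older
adults over a neighborhood, as a weighted linear combination of ordinal
layers on a common raster grid:

PA(cell) = Σᵢ wᵢ · rᵢ(cell), with Σ wᵢ = 1 and rᵢ ∈ {1,…,5}.

Three kinds of variables enter the overlay:

1. **Bench proximity** — network distance from each cell to the nearest
   public bench. All surveyed bench kinds (formal street benches, bus-stop
   benches, informal seating such as low walls) count as sources: any seat
   can serve as a relay bench during a walk. Kind is kept as metadata only.
2. **Service/facility proximity** — network distance to the nearest site in
   five fixed groups (health services; municipal services and amenities;
   social and cultural facilities; shopping; schools and childcare). The
   chronic-disease profile splits this into a *health services* layer and an
   *other services* layer; the other profiles use one *all services* layer.
   Subtypes are free text; only the group drives the model.
3. **Slope** — percent gradient from a DTM.

The network itself is the impedance substrate, not a weighted layer: no
connectivity metric enters the overlay.

### Proximity: distance fields and rasterization

The pedestrian graph is undirected (walking is symmetric), with one node per
merged line endpoint and one edge per line feature. Endpoint merging uses a
0.05 m tolerance — safe under a 5 m analysis grid. Off-graph points
(benches, facilities) snap to the nearest edge within 25 m (about half a
street width); mid-edge snaps split the edge's cost proportionally rather
than rounding to a node. Proximity is a multi-source Dijkstra field: each
node's minimum network distance to any source. Rasterization assigns each
cell the field value at its nearest node within 100 m (one Very-High band
width) plus the straight-line cell-to-node distance; cells with no node in
range are *unreached* and fall to level 1. Nearest-node ties are resolved by
the KD-tree's deterministic ordering; the test oracle accepts any minimizer.

Edge impedance is meters by default — the distance band tables are metric —
but a walking-minutes metric is available (CLI `service-area --metric
minutes`) using a two-regime speed model: 4.3 km/h on gradients up to 9°
and 4.0 km/h beyond. The threshold is stored as percent, tan(9°)·100 ≈
15.84 %, with "≤ threshold → moderate speed", so gradients of 15.8 % walk at
4.3 km/h and 15.9 % at 4.0 km/h. Edge gradients are unsigned
(|Δelevation|/length), one value per edge from its endpoint elevations —
commensurate with the 25 m DTM resolution the model assumes; no
densification is attempted.

### Slope

Percent slope uses the Horn 3×3 finite-difference operator (the common GIS
default), exact on planes. Borders are handled by edge replication so small
rasters keep full coverage; note this halves the reported gradient of a
tilted plane in the outermost row/column — a bias confined to one DTM cell
at the study edge. Any 3×3 window touching nodata yields nodata. Slope is
computed at DTM resolution and bilinearly resampled onto the analysis grid;
resampling the slope rather than the elevations avoids re-differentiating
interpolated values. No DTM artifact correction is applied: vegetation or
embankment errors in the input propagate to the slope layer as-is.

### Reclassification and overlay

The five ordinal levels Very Low…Very High map to 1…5 — the minimal equally
spaced scores consistent with a common rating scale. Band conventions:
distance bands are half-open [lo, hi) m, so a value exactly on a printed
boundary takes the next band (100 m → High); slope bands are upper-closed
(lo, hi] %, matching printed two-decimal edges (3.01–5.00 ⇒ (3, 5]). Values
beyond the last band, and unreached cells, take level 1 — extending the
worst band is the conservative choice. Weights must be non-negative and sum
to 1 (tolerance 1e-9); layer names must exactly match the profile's weight
keys. Continuous PA is quantized to classes by nearest integer with ties
(x.5) rounding up. Area summaries report all five classes as percentages of
unmasked cells, exact until presentation. The module contains no randomness;
reproducibility is structural.

The statutory predicate `is_statutory(g)` implements the French legal
definition of an obstacle-free path: gradient ≤ 5 %.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| analysis cell size | 5 | m | fine-scale neighborhood analysis |
| node merge tolerance | 0.05 | m | sub-decimeter, safe under 5 m cells |
| source snap radius | 25 | m | ~half a street width |
| off-network radius | 100 | m | one Very-High band width |
| moderate / steep speed | 4.3 / 4.0 | km/h | averaged older-adult speed profiles |
| speed threshold | tan 9° ≈ 15.84 | % | regime change at 9° |
| statutory bound | 5 | % | legal obstacle-free definition |

Profiles and band tables are overridable via a YAML config validated on
load; the built-ins are in `builtin_profiles()` / `builtin_reclass_tables()`.

## Synthetic neighborhoods

The generator emulates the structural contrast between two urban forms. The
street pattern is an orthogonal grid over the extent, optionally thinned
into suburban loops by removing ~40 % of edges under a connectivity
constraint. Amenities are sampled uniformly along total street length with a
≤5 m lateral offset — the simplest model of street-facing amenities — so
every generated site snaps to the network. Terrain is flat, a ramp of given
grade, or Gaussian-smoothed noise with a given amplitude and length scale,
realized on a 25 m DTM covering the network with a one-spacing margin. One
seeded generator drives each call; identical configs give byte-identical
GeoJSON/ASCII outputs, and the seed is recorded in the simulation metadata.

Preset conditions: `b_like` is a dense grid (100 m spacing) on flat terrain
with 169 benches and 45 facilities; `a_like` is sparse loops (200 m spacing)
on a 10 % ramp with 53 benches and 27 facilities, the facility counts
distributed over the five groups per the surveyed inventories. The 800 m ×
800 m extents are the package's own choice, sized so a full three-profile
run on both presets completes in seconds at the 5 m grid.

What the generator does **not** emulate: realistic street morphology (curves,
culs-de-sac, crossings), clustered commercial frontage, correlated
amenity–terrain placement, DTM artifacts, or study-area edge effects
(opportunities just outside the extent are invisible, so border cells are
underestimated). Passing tests therefore demonstrate the pipeline's
correctness and its qualitative discrimination between dense-flat and
sparse-sloped forms, not calibrated area percentages for any real
neighborhood.

## Verification

Distance fields are cross-checked against an independent per-source
Bellman-Ford oracle on random geometric graphs; the full overlay is
cross-checked against a per-cell brute-force recomputation (direct
nearest-node search, scalar band rules) to 1e-9. Invariants under test:
area percentages sum to 100 %; min rᵢ ≤ PA ≤ max rᵢ cell-wise; slope is
affine- and similarity-invariant; the health/other service split at equal
half-weights equals an unsplit run; adding an edge never increases any
distance; and the dense flat preset's mean PA is ≥ the sparse sloped
preset's for all three profiles across ten seeds.

## Known limitations

Turn restrictions, crossing penalties, directed uphill/downhill asymmetry,
gravity-decay accessibility, facility capacity/opening hours, and
edge-effect buffering are out of scope. Parallel street records between the
same pair of nodes are collapsed to the shorter one (the graph is simple).
GeoTIFF is not read or written; Esri ASCII grid is the raster format.
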