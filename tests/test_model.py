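"""Reclassification, weighted overlay, quantization, area summaries, run_model."""

import math

import numpy as np
import pytest

from pedaccess import (
    AnalysisGrid,
    LevelLayer,
    ProfileWeights,
    area_summary,
    build_network,
    builtin_profiles,
    builtin_reclass_tables,
    distance_field,
    distance_raster,
    load_inventory,
    quantize,
    reclassify,
    run_model,
    select_sources,
    weighted_sum,
)
from pedaccess.model import load_model_config

from conftest import (
    X0,
    Y0,
    bench_point,
    facility_point,
    flat_dtm,
    grid_town_features,
)
from test_network import brute_force_min_distance
from pedaccess.geojson import line_feature


class TestProfiles:
    def test_builtin_weights(self):
        p = builtin_profiles()
        assert p["healthy"].weights == {"benches": 0.45, "all_services": 0.45, "slope": 0.10}
        assert p["chronic_disease"].weights == {
            "benches": 0.30, "health_services": 0.40, "other_services": 0.10, "slope": 0.20,
        }
        assert p["reduced_mobility"].weights == {"benches": 0.30, "all_services": 0.30, "slope": 0.40}
        assert p["chronic_disease"].split_services
        assert not p["healthy"].split_services

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ProfileWeights("bad", {"benches": 0.5, "all_services": 0.4, "slope": 0.05})

    def test_split_profile_requires_both_service_keys(self):
        with pytest.raises(ValueError):
            ProfileWeights(
                "bad", {"benches": 0.5, "health_services": 0.4, "slope": 0.1},
                split_services=True,
            )


class TestReclassify:
    @pytest.mark.parametrize(
        "variable,value,level",
        [
            ("benches", 50.0, 5),
            ("benches", 100.0, 4),   # half-open [lo, hi): boundary goes down-band
            ("benches", 400.0, 3),
            ("benches", 1500.0, 1),  # beyond the last band
            ("benches", math.inf, 1),  # unreached
            ("all_services", 400.0, 3),
            ("all_services", 700.0, 2),
            ("slope", 0.0, 5),
            ("slope", 3.0, 5),       # upper-closed (lo, hi]
            ("slope", 4.0, 4),
            ("slope", 5.0, 4),
            ("slope", 12.5, 1),
        ],
    )
    def test_band_lookup(self, variable, value, level):
        table = builtin_reclass_tables()[variable]
        assert table.lookup(np.array([value]))[0] == level

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            builtin_reclass_tables()["benches"].lookup(np.array([-1.0]))

    def test_nodata_propagates(self):
        grid = AnalysisGrid(X0, Y0, 1, 2, 5.0)
        layer = reclassify(
            np.array([[50.0, np.nan]]), builtin_reclass_tables()["benches"], grid
        )
        assert layer.values[0, 0] == 5
        assert np.isnan(layer.values[0, 1])

    def test_non_contiguous_bands_rejected(self):
        from pedaccess.model import ReclassTable

        with pytest.raises(ValueError, match="contiguous"):
            ReclassTable("x", [(0, 100, 5), (200, 300, 4)])


def layer(grid, value_array, name):
    return LevelLayer(grid, np.asarray(value_array, dtype=float), name)


class TestWeightedSum:
    def test_convexity_all_fives(self):
        grid = AnalysisGrid(X0, Y0, 2, 2, 5.0)
        layers = {
            "benches": layer(grid, np.full((2, 2), 5), "benches"),
            "all_services": layer(grid, np.full((2, 2), 5), "all_services"),
            "slope": layer(grid, np.full((2, 2), 5), "slope"),
        }
        surf = weighted_sum(layers, builtin_profiles()["healthy"])
        assert np.allclose(surf.pa, 5.0)

    def test_healthy_worked_example(self):
        grid = AnalysisGrid(X0, Y0, 1, 1, 5.0)
        layers = {
            "benches": layer(grid, [[5]], "benches"),
            "all_services": layer(grid, [[3]], "all_services"),
            "slope": layer(grid, [[1]], "slope"),
        }
        surf = weighted_sum(layers, builtin_profiles()["healthy"])
        assert surf.pa[0, 0] == pytest.approx(3.70)
        assert surf.classes[0, 0] == 4

    def test_chronic_worked_example(self):
        grid = AnalysisGrid(X0, Y0, 1, 1, 5.0)
        layers = {
            "benches": layer(grid, [[2]], "benches"),
            "health_services": layer(grid, [[5]], "health_services"),
            "other_services": layer(grid, [[1]], "other_services"),
            "slope": layer(grid, [[4]], "slope"),
        }
        surf = weighted_sum(layers, builtin_profiles()["chronic_disease"])
        assert surf.pa[0, 0] == pytest.approx(3.50)

    def test_missing_layer_named(self):
        grid = AnalysisGrid(X0, Y0, 1, 1, 5.0)
        layers = {"benches": layer(grid, [[5]], "benches")}
        with pytest.raises(ValueError, match="all_services"):
            weighted_sum(layers, builtin_profiles()["healthy"])

    def test_convex_bound_random_layers(self):
        rng = np.random.default_rng(11)
        grid = AnalysisGrid(X0, Y0, 8, 8, 5.0)
        for _ in range(20):
            vals = {
                name: rng.integers(1, 6, size=(8, 8))
                for name in ("benches", "all_services", "slope")
            }
            w = rng.dirichlet(np.ones(3))
            weights = ProfileWeights(
                "rand", dict(zip(("benches", "all_services", "slope"), map(float, w)))
            )
            layers = {n: layer(grid, v, n) for n, v in vals.items()}
            surf = weighted_sum(layers, weights)
            stack = np.stack(list(vals.values()))
            assert np.all(surf.pa >= stack.min(axis=0) - 1e-9)
            assert np.all(surf.pa <= stack.max(axis=0) + 1e-9)

    def test_split_weights_equal_unsplit(self):
        # both half-weights on identical service layers == one unsplit layer
        rng = np.random.default_rng(5)
        grid = AnalysisGrid(X0, Y0, 6, 6, 5.0)
        svc = rng.integers(1, 6, size=(6, 6))
        bench = rng.integers(1, 6, size=(6, 6))
        slope = rng.integers(1, 6, size=(6, 6))
        split = weighted_sum(
            {
                "benches": layer(grid, bench, "benches"),
                "health_services": layer(grid, svc, "health_services"),
                "other_services": layer(grid, svc, "other_services"),
                "slope": layer(grid, slope, "slope"),
            },
            ProfileWeights(
                "split",
                {"benches": 0.3, "health_services": 0.25, "other_services": 0.25, "slope": 0.2},
                split_services=True,
            ),
        )
        unsplit = weighted_sum(
            {
                "benches": layer(grid, bench, "benches"),
                "all_services": layer(grid, svc, "all_services"),
                "slope": layer(grid, slope, "slope"),
            },
            ProfileWeights("unsplit", {"benches": 0.3, "all_services": 0.5, "slope": 0.2}),
        )
        assert np.allclose(split.pa, unsplit.pa, atol=1e-12)


class TestQuantize:
    @pytest.mark.parametrize("pa,cls", [(3.70, 4), (2.5, 3), (5.0, 5), (1.0, 1), (1.49, 1)])
    def test_nearest_integer_ties_up(self, pa, cls):
        assert quantize(np.array([pa]))[0] == cls

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[1, 5\]"):
            quantize(np.array([0.5]))


class TestAreaSummary:
    def test_two_by_two(self):
        grid = AnalysisGrid(X0, Y0, 2, 2, 5.0)
        s = area_summary(np.array([[5, 5], [3, 1]]), grid)
        assert s == {5: 50.0, 4: 0.0, 3: 25.0, 2: 0.0, 1: 25.0}

    def test_uniform(self):
        grid = AnalysisGrid(X0, Y0, 3, 3, 5.0)
        s = area_summary(np.full((3, 3), 2), grid)
        assert s[2] == 100.0

    def test_mask_restricts_area(self):
        mask = np.array([[True, True], [False, False]])
        grid = AnalysisGrid(X0, Y0, 2, 2, 5.0, mask=mask)
        s = area_summary(np.array([[5, 3], [1, 1]]), grid)
        assert s[5] == 50.0 and s[3] == 50.0 and s[1] == 0.0

    def test_fully_masked_rejected(self):
        grid = AnalysisGrid(X0, Y0, 2, 2, 5.0, mask=np.zeros((2, 2), bool))
        with pytest.raises(ValueError, match="masked"):
            area_summary(np.ones((2, 2)), grid)

    def test_percentages_conserve(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            shape = (int(rng.integers(1, 15)), int(rng.integers(1, 15)))
            grid = AnalysisGrid(X0, Y0, shape[0], shape[1], 5.0)
            s = area_summary(rng.integers(1, 6, size=shape), grid)
            assert sum(s.values()) == pytest.approx(100.0, abs=1e-9)


def assert_pa_matches_brute_force(surf, net, inv, grid, profile, slope_level=5):
    """Independent per-cell recomputation of PA on a flat-terrain fixture:
    nearest node by direct search, network distances by per-source
    Bellman-Ford, band levels by scalar if-chains."""
    weights = builtin_profiles()[profile].weights
    node_ids = sorted(net.graph.nodes)
    coords = {n: net.node_xy(n) for n in node_ids}

    def node_of(pt):
        return min(node_ids, key=lambda n: math.dist(coords[n], pt))

    fields = {
        var: brute_force_min_distance(
            net, [node_of(p) for p in select_sources(inv, var)]
        )
        for var in weights
        if var != "slope"
    }

    def bench_level(d):
        for hi, lv in ((100, 5), (300, 4), (500, 3), (700, 2), (1000, 1)):
            if d < hi:
                return lv
        return 1

    def service_level(d):
        for hi, lv in ((100, 5), (300, 4), (600, 3), (800, 2), (1000, 1)):
            if d < hi:
                return lv
        return 1

    X, Y = grid.cell_centers()
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            p = (X[r, c], Y[r, c])
            dists = {n: math.dist(coords[n], p) for n in node_ids}
            d0 = min(dists.values())
            # the nearest-node rule is ambiguous under exact ties:
            # accept the PA implied by any minimizer
            candidates = []
            for near in (n for n, d in dists.items() if d < d0 + 1e-9):
                expected = weights["slope"] * slope_level
                for var, w in weights.items():
                    if var == "slope":
                        continue
                    d = fields[var][near] + d0
                    lv = bench_level(d) if var == "benches" else service_level(d)
                    expected += w * lv
                candidates.append(expected)
            assert any(
                surf.pa[r, c] == pytest.approx(e, abs=1e-9) for e in candidates
            )


def town_with_amenities(bench_nodes, health_nodes, other_nodes, n=5, spacing=100.0):
    """5x5 grid town with amenities placed exactly at named (i, j) corners."""
    net = build_network(grid_town_features(n, spacing))
    def pt(ij):
        return (X0 + ij[0] * spacing, Y0 + ij[1] * spacing)
    benches = [bench_point(*pt(ij), i=i) for i, ij in enumerate(bench_nodes)]
    facs = [facility_point(*pt(ij), "health_services", i) for i, ij in enumerate(health_nodes)]
    facs += [
        facility_point(*pt(ij), "shopping", 100 + i) for i, ij in enumerate(other_nodes)
    ]
    inv = load_inventory(facs, benches)
    return net, inv


class TestRunModel:
    def test_saturated_town_all_very_high(self):
        corners = [(i, j) for i in range(5) for j in range(5)]
        net, inv = town_with_amenities(corners, corners, corners)
        grid = AnalysisGrid.from_bounds(*_bounds(net), cellsize=20.0)
        surf, summary = run_model(net, flat_dtm(net.bounds()), inv, grid, "healthy")
        assert np.all(surf.classes == 5)
        assert summary[5] == 100.0

    def test_pa_non_increasing_with_distance_from_single_corner(self):
        net, inv = town_with_amenities([(0, 0)], [(0, 0)], [(0, 0)])
        grid = AnalysisGrid.from_bounds(*_bounds(net), cellsize=20.0)
        surf, _ = run_model(net, flat_dtm(net.bounds()), inv, grid, "healthy")
        fld = distance_field(net, [(X0, Y0)])
        dvals = distance_raster(fld, net, grid)
        order = np.argsort(dvals, axis=None)
        pa_sorted = surf.pa.ravel()[order]
        assert np.all(np.diff(pa_sorted) <= 1e-9)

    def test_isolated_health_facility_scores_very_low(self):
        # health facility on a detached path segment 2 km away: unreachable
        feats = grid_town_features(5, 100.0)
        feats.append(line_feature([(X0 + 2000.0, Y0), (X0 + 2100.0, Y0)]))
        net = build_network(feats)
        far_fac = [facility_point(X0 + 2050.0, Y0, "health_services", 0)]
        near = [facility_point(X0 + 100.0, Y0, "shopping", 1)]
        inv = load_inventory(far_fac + near, [bench_point(X0, Y0)])
        grid = AnalysisGrid.from_bounds(X0, Y0, X0 + 400.0, Y0 + 400.0, cellsize=20.0)
        fld = distance_field(net, select_sources(inv, "health_services"))
        vals = distance_raster(fld, net, grid)
        level = reclassify(vals, builtin_reclass_tables()["health_services"], grid)
        assert np.all(level.values == 1)
        surf, _ = run_model(net, flat_dtm(net.bounds()), inv, grid, "chronic_disease")
        # PA = .3*b + .4*1 + .1*o + .2*s everywhere: health contributes its floor
        assert np.nanmax(surf.pa) <= 0.3 * 5 + 0.4 * 1 + 0.1 * 5 + 0.2 * 5 + 1e-9

    @pytest.mark.parametrize("profile", ["healthy", "chronic_disease"])
    def test_matches_per_cell_brute_force(self, profile):
        """Full-pipeline oracle: recompute PA per cell with scalar band
        rules, per-source Bellman-Ford and direct nearest-node search."""
        net, inv = town_with_amenities(
            bench_nodes=[(0, 0), (2, 3), (4, 4)],
            health_nodes=[(1, 1)],
            other_nodes=[(4, 0), (0, 4)],
        )
        grid = AnalysisGrid.from_bounds(*_bounds(net), cellsize=20.0)
        dtm = flat_dtm(net.bounds())
        surf, _ = run_model(net, dtm, inv, grid, profile)
        assert_pa_matches_brute_force(surf, net, inv, grid, profile)


def _bounds(net):
    return net.bounds()


class TestConfig:
    def test_custom_profile_and_bands(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text(
            "profiles:\n"
            "  frail: {benches: 0.5, all_services: 0.2, slope: 0.3}\n"
            "variables:\n"
            "  benches:\n"
            "    units: m\n"
            "    closed: left\n"
            "    bands: [[0, 50, 5], [50, 150, 4], [150, 300, 3], [300, 500, 2], [500, 800, 1]]\n"
        )
        profiles, tables = load_model_config(cfg)
        assert profiles["frail"].weights["benches"] == 0.5
        assert tables["benches"].lookup(np.array([100.0]))[0] == 4
        # untouched tables fall back to the built-ins
        assert tables["slope"].lookup(np.array([4.0]))[0] == 4

    def test_invalid_custom_weights_rejected(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text("profiles:\n  bad: {benches: 0.9, all_services: 0.9, slope: 0.2}\n")
        with pytest.raises(ValueError, match="sum to 1"):
            load_model_config(cfg)
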