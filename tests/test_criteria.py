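"""Terrain derivatives, threshold normalization, discrete scores,
vegetation metrics and fire history."""

import math

import numpy as np
import pytest
import shapely

from postfire_mca.criteria import (
    ARIDITY_SCORES,
    ASPECT_SCORES,
    EROSION_THRESHOLDS,
    SEVERITY_VRP_SCORES,
    STRATEGY_SCORES,
    ContinuousCriterionSpec,
    FireHistoryCell,
    SpeciesRecord,
    VegetationPolygon,
    aspect_to_sector,
    derive_slope_aspect,
    fire_history_from_perimeters,
    normalize_continuous,
    percent_resprouters,
    rasterize_polygons,
    read_vegetation_geojson,
    regeneration_capacity,
    score_discrete,
    score_fire_history,
    score_raster,
    write_vegetation_geojson,
)
from postfire_mca.errors import (
    GridShapeError,
    ScoreLookupError,
    UndefinedRCError,
)
from postfire_mca.raster import Raster


def plane_dem(a, b, n=12, cellsize=10.0):
    """DEM for z = a*x + b*y (x east, y north)."""
    xs = (np.arange(n) + 0.5) * cellsize
    ys = (n - np.arange(n) - 0.5) * cellsize  # row 0 is northmost
    zz = a * xs[None, :] + b * ys[:, None]
    return Raster(zz, west=0, north=n * cellsize, cellsize=cellsize)


class TestSlopeAspect:
    def test_flat_dem(self):
        slope, aspect = derive_slope_aspect(plane_dem(0, 0))
        inner = slope.data[1:-1, 1:-1]
        np.testing.assert_allclose(inner, 0.0)
        assert np.isnan(aspect.data[1:-1, 1:-1]).all()

    def test_plane_rising_south_faces_north(self):
        # z increases southward by 1 m per 10 m: 10 % slope, downslope
        # direction (the face of the slope) points due north
        slope, aspect = derive_slope_aspect(plane_dem(0, -0.1))
        np.testing.assert_allclose(slope.data[1:-1, 1:-1], 10.0, atol=1e-9)
        np.testing.assert_allclose(aspect.data[1:-1, 1:-1] % 360.0, 0.0, atol=1e-9)

    def test_rotating_plane_rotates_aspect_and_keeps_slope(self):
        s1, a1 = derive_slope_aspect(plane_dem(0.1, 0))   # rises east -> faces west
        s2, a2 = derive_slope_aspect(plane_dem(0, 0.1))   # rises north -> faces south
        np.testing.assert_allclose(a1.data[1:-1, 1:-1], 270.0, atol=1e-9)
        np.testing.assert_allclose(a2.data[1:-1, 1:-1], 180.0, atol=1e-9)
        np.testing.assert_allclose(s1.data[1:-1, 1:-1], s2.data[1:-1, 1:-1], atol=1e-9)

    def test_analytic_gradient_match(self):
        a, b = 0.07, -0.13
        slope, _ = derive_slope_aspect(plane_dem(a, b))
        np.testing.assert_allclose(
            slope.data[1:-1, 1:-1], 100 * math.hypot(a, b), atol=1e-6
        )

    def test_borders_are_nodata(self):
        slope, aspect = derive_slope_aspect(plane_dem(0.1, 0.1))
        assert np.isnan(slope.data[0]).all() and np.isnan(slope.data[:, -1]).all()

    def test_degenerate_grid_rejected(self):
        with pytest.raises(GridShapeError):
            derive_slope_aspect(Raster(np.zeros((1, 5)), 0, 10, 10))

    @pytest.mark.parametrize(
        "deg,sector",
        [(0, "N"), (22.4, "N"), (22.6, "NE"), (90, "E"), (135, "SE"),
         (180, "S"), (225, "SW"), (270, "W"), (315, "NW"), (350, "N"),
         (float("nan"), "FLAT")],
    )
    def test_sectors(self, deg, sector):
        assert aspect_to_sector(deg) == sector


class TestNormalizeContinuous:
    slope_spec = EROSION_THRESHOLDS["slope"]

    @pytest.mark.parametrize(
        "value,expected",
        [(0, 0.0), (9, 0.0), (44.5, 0.5), (80, 1.0), (100, 1.0)],
    )
    def test_slope_thresholds(self, value, expected):
        assert normalize_continuous(value, self.slope_spec) == pytest.approx(expected)

    def test_monotone_and_idempotent(self):
        spec = ContinuousCriterionSpec("x", 0.0, 1.0)
        xs = np.linspace(-1, 2, 101)
        ys = normalize_continuous(xs, spec)
        assert np.all(np.diff(ys) >= 0)
        np.testing.assert_allclose(normalize_continuous(ys, spec), ys, atol=1e-12)

    def test_nan_propagates(self):
        assert math.isnan(normalize_continuous(float("nan"), self.slope_spec))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ContinuousCriterionSpec("bad", 5.0, 5.0)

    def test_resprouter_saturation_at_40_percent_cover(self):
        spec = EROSION_THRESHOLDS["resprouters"]
        assert normalize_continuous(0.4, spec) == pytest.approx(1.0)
        assert normalize_continuous(0.2, spec) == pytest.approx(0.5)


def veg_polygon(records, pid="p"):
    trees = [r for r in records if r.stratum == "tree"]
    shrub = next((r for r in records if r.stratum == "shrub"), None)
    grass = next((r for r in records if r.stratum == "grass"), None)
    return VegetationPolygon(
        polygon_id=pid,
        geometry=shapely.box(0, 0, 100, 100),
        tree_records=trees,
        shrub_record=shrub,
        grass_record=grass,
    )


class TestVegetationMetrics:
    def test_full_resprouter_cover(self):
        p = veg_polygon([SpeciesRecord("q", "tree", 1.0, "resprouter")])
        assert percent_resprouters(p) == pytest.approx(1.0)

    def test_no_resprouters(self):
        p = veg_polygon([SpeciesRecord("p", "tree", 0.8, "seeder")])
        assert percent_resprouters(p) == 0.0

    def test_partial_resprouter_sum(self):
        p = veg_polygon(
            [
                SpeciesRecord("a", "tree", 0.2, "resprouter"),
                SpeciesRecord("b", "shrub", 0.1, "resprouter"),
                SpeciesRecord("c", "grass", 0.3, "seeder"),
            ]
        )
        assert percent_resprouters(p) == pytest.approx(0.30)

    def test_adding_resprouter_never_decreases(self):
        base = [SpeciesRecord("a", "tree", 0.3, "seeder")]
        more = base + [SpeciesRecord("b", "shrub", 0.2, "resprouter")]
        assert percent_resprouters(veg_polygon(more)) >= percent_resprouters(
            veg_polygon(base)
        )

    def test_rc_single_resprouter(self):
        p = veg_polygon([SpeciesRecord("q", "tree", 1.0, "resprouter")])
        assert regeneration_capacity(p) == pytest.approx(1.0)

    def test_rc_hand_example(self):
        p = veg_polygon(
            [
                SpeciesRecord("t1", "tree", 0.4, "resprouter"),       # score 1
                SpeciesRecord("t2", "tree", 0.2, "postfire_seeder"),  # score 2
                SpeciesRecord("s", "shrub", 0.2, "postfire_seeder"),  # score 2
                SpeciesRecord("g", "grass", 0.2, "seeder"),           # score 3
            ]
        )
        assert regeneration_capacity(p) == pytest.approx(1.8)

    def test_rc_all_seeders(self):
        p = veg_polygon(
            [
                SpeciesRecord("a", "tree", 0.5, "seeder"),
                SpeciesRecord("g", "grass", 0.3, "seeder"),
            ]
        )
        assert regeneration_capacity(p) == pytest.approx(3.0)

    def test_rc_zero_cover_undefined(self):
        p = veg_polygon([SpeciesRecord("a", "tree", 0.0, "seeder")])
        with pytest.raises(UndefinedRCError):
            regeneration_capacity(p)

    def test_rc_convex_combination_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            recs = []
            covers = rng.dirichlet(np.ones(3)) * rng.uniform(0.3, 1.0)
            strategies = rng.choice(
                ["resprouter", "postfire_seeder", "seeder"], size=3
            )
            for k, (stratum, c, s) in enumerate(
                zip(("tree", "shrub", "grass"), covers, strategies)
            ):
                recs.append(SpeciesRecord(f"sp{k}", stratum, float(c), str(s)))
            rc = regeneration_capacity(veg_polygon(recs))
            scores = [STRATEGY_SCORES.lookup(s) for s in strategies]
            assert min(scores) - 1e-9 <= rc <= max(scores) + 1e-9

    def test_polygon_invariants(self):
        with pytest.raises(ValueError):
            veg_polygon(
                [
                    SpeciesRecord("a", "tree", 0.6, "seeder"),
                    SpeciesRecord("b", "shrub", 0.6, "seeder"),
                ]
            )
        with pytest.raises(ValueError):
            VegetationPolygon(
                "p",
                shapely.box(0, 0, 1, 1),
                tree_records=[SpeciesRecord(f"t{i}", "tree", 0.1, "seeder") for i in range(4)],
            )


class TestDiscreteScores:
    @pytest.mark.parametrize(
        "sector,score",
        [("N", 1), ("NE", 1), ("NW", 1), ("E", 2), ("W", 2),
         ("SE", 2), ("SW", 2), ("S", 3), ("FLAT", 1)],
    )
    def test_aspect_scores(self, sector, score):
        assert score_discrete(sector, ASPECT_SCORES) == score

    @pytest.mark.parametrize(
        "ai,score",
        [(0.15, 3), (0.2, 3), (0.21, 2), (0.35, 2), (0.5, 2), (0.51, 1), (0.8, 1)],
    )
    def test_aridity_scores(self, ai, score):
        assert score_discrete(ai, ARIDITY_SCORES) == score

    @pytest.mark.parametrize(
        "strategy,score",
        [("resprouter", 1), ("postfire_seeder", 2), ("seeder", 3)],
    )
    def test_strategy_scores(self, strategy, score):
        assert score_discrete(strategy, STRATEGY_SCORES) == score

    @pytest.mark.parametrize(
        "dnbr,score",
        [(0.05, 1), (0.2, 1), (0.265, 1), (0.27, 2), (0.5, 2), (0.655, 2),
         (0.66, 2), (0.661, 3), (0.9, 3)],
    )
    def test_severity_recovery_scores_are_gapless(self, dnbr, score):
        assert score_discrete(dnbr, SEVERITY_VRP_SCORES) == score

    def test_unknown_category_rejected(self):
        with pytest.raises(ScoreLookupError):
            score_discrete("SSW", ASPECT_SCORES)

    def test_score_raster_matches_scalar_lookup(self):
        vals = np.array([[0.1, 0.3, 0.55], [0.05, 0.22, 0.7]])
        r = Raster(vals, 0, 20, 10)
        out = score_raster(r, ARIDITY_SCORES).data
        expected = np.vectorize(lambda v: score_discrete(v, ARIDITY_SCORES))(vals)
        np.testing.assert_allclose(out, expected)


class TestFireHistory:
    @pytest.mark.parametrize(
        "n,years,score",
        [
            (1, 20, 1),
            (0, float("inf"), 1),
            (2, 12, 2),
            (3, 20, 3),   # frequency alone suffices
            (1, 5, 3),    # short interval alone suffices (max rule)
            (2, 5, 3),
            (1, 12, 2),
        ],
    )
    def test_max_rule(self, n, years, score):
        assert score_fire_history(FireHistoryCell(n, years)) == score

    def test_explicit_matrix_overrides_combination(self):
        # multiplicative-style matrix instead of max
        matrix = [[1, 1, 2], [1, 2, 3], [2, 3, 3]]
        assert score_fire_history(FireHistoryCell(1, 5), matrix) == 2

    def test_monotone_in_frequency_and_recency(self):
        for years in (5, 12, 20):
            scores = [
                score_fire_history(FireHistoryCell(n, years)) for n in (1, 2, 3, 4)
            ]
            assert scores == sorted(scores)
        for n in (1, 2, 3):
            scores = [
                score_fire_history(FireHistoryCell(n, y)) for y in (20, 12, 5)
            ]
            assert scores == sorted(scores)

    def test_unburned_cell_invariant(self):
        with pytest.raises(ValueError):
            FireHistoryCell(0, 12.0)

    def test_from_perimeters(self):
        template = Raster(np.zeros((4, 4)), 0, 40, 10)
        west = shapely.box(0, 0, 20, 40)
        all_area = shapely.box(0, 0, 40, 40)
        n, ys = fire_history_from_perimeters(
            [(west, 2016), (all_area, 2009), (west, 1985)],
            template,
            reference_year=2021,
        )
        # west half: fires 2016 and 2009 in window, 1985 excluded
        assert n.data[0, 0] == 2 and ys.data[0, 0] == 5
        # east half: only the 2009 fire
        assert n.data[0, 3] == 1 and ys.data[0, 3] == 12
        template_far = Raster(np.zeros((2, 2)), 1000, 1040, 10)
        n2, ys2 = fire_history_from_perimeters([(west, 2016)], template_far, 2021)
        assert (n2.data == 0).all() and np.isinf(ys2.data).all()


class TestRasterizeAndGeoJSON:
    def test_center_membership_matches_brute_force(self):
        template = Raster(np.zeros((6, 6)), 0, 60, 10)
        poly = shapely.Polygon([(5, 5), (48, 12), (40, 52), (8, 40)])
        out = rasterize_polygons([(poly, 2.0)], template).data
        from shapely.geometry import Point

        for r in range(6):
            for c in range(6):
                x, y = (c + 0.5) * 10, 60 - (r + 0.5) * 10
                expected = 2.0 if poly.contains(Point(x, y)) else np.nan
                if np.isnan(expected):
                    assert np.isnan(out[r, c])
                else:
                    assert out[r, c] == expected

    def test_vegetation_geojson_roundtrip(self, tmp_path):
        polys = [
            veg_polygon(
                [
                    SpeciesRecord("Quercus", "tree", 0.4, "resprouter"),
                    SpeciesRecord("Cistus", "shrub", 0.3, "postfire_seeder"),
                ],
                pid="poly_1",
            )
        ]
        path = write_vegetation_geojson(polys, tmp_path / "veg.geojson")
        back = read_vegetation_geojson(path)
        assert back[0].polygon_id == "poly_1"
        assert percent_resprouters(back[0]) == pytest.approx(0.4)
        assert regeneration_capacity(back[0]) == pytest.approx(
            regeneration_capacity(polys[0])
        )
        assert back[0].geometry.equals(polys[0].geometry)
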