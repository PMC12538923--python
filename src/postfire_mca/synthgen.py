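"""Seeded synthetic fixtures for the whole assessment pipeline.

The generator emulates the study inputs at desk scale: a smoothed random
DEM, pre/post-fire reflectance stacks with an elliptical burn scar whose
dNBR follows a configured severity mixture, a vegetation-polygon
tessellation with per-stratum species records, erodibility and aridity
rasters, historical fire perimeters, AHP judgment sets for several
participants, and field plots whose erosion observations and cover
estimates are stochastically tied to the true composite indices.

Everything is deterministic per (seed, parameters): each product draws
from its own child generator so regenerating one file never perturbs
another.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely import affinity
from shapely.geometry import Point

from . import fieldval
from .ahp import (
    ComparisonMatrix,
    SAATY_SCALE,
    WeightVector,
    aggregate_weights,
    build_comparison_matrix,
    derive_weights,
    write_judgments_csv,
)
from .composite import SER_CRITERIA, VRP_CRITERIA, CompositeIndexMap
from .criteria import (
    SpeciesRecord,
    VegetationPolygon,
    write_perimeters_geojson,
    write_vegetation_geojson,
)
from .fieldval import EROSION_SCORES, FieldPlot, write_plots_csv
from .raster import Raster, write_ascii_grid
from .spectral import BandStack, SceneMeta, write_scene_catalog
from .workflow import AssessmentInputs, compute_criterion_layers, compute_indices

#: Species pool per post-fire strategy (synthetic community, Mediterranean
#: flavoured names only for readability of the fixtures).
SPECIES_POOL = {
    "resprouter": ("Quercus pyrenaica", "Erica arborea", "Arbutus unedo"),
    "postfire_seeder": ("Pinus pinaster", "Cistus ladanifer", "Halimium lasianthum"),
    "seeder": ("Pinus sylvestris", "Genista cinerascens", "Agrostis truncatula"),
}

_STRATEGIES = ("resprouter", "postfire_seeder", "seeder")

# child-rng stream ids
_TERRAIN, _BANDS, _VEG, _KFACT, _ARID, _HIST, _JUDGE, _PLOTS = range(8)


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study area.

    Defaults mirror the study conditions: a 10 m analysis grid, a 5 m
    DEM, two field localities with 11 and 13 plots, severity mixture
    dominated by moderate burns, weight perturbations judged by five
    participants.
    """

    seed: int = 0
    n_rows: int = 96
    n_cols: int = 96
    cellsize: float = 10.0
    dem_cellsize: float = 5.0
    west: float = 0.0
    north: float = 960.0
    relief_amplitude_m: float = 60.0
    terrain_smoothing_m: float = 80.0
    # burn scar: ellipse as fractions of the extent
    scar_center_frac: tuple[float, float] = (0.5, 0.5)
    scar_radii_frac: tuple[float, float] = (0.34, 0.24)
    scar_rotation_deg: float = 25.0
    # low / moderate / high area fractions inside the scar
    severity_mixture: tuple[float, float, float] = (0.30, 0.45, 0.25)
    fire_year: int = 2021
    fire_start: dt.date = dt.date(2021, 8, 16)
    fire_end: dt.date = dt.date(2021, 8, 31)
    # mean cover fraction per strategy (resprouter, post-fire seeder, seeder)
    strategy_cover: tuple[float, float, float] = (0.35, 0.30, 0.25)
    cover_concentration: float = 60.0
    n_tile_rows: int = 6
    n_tile_cols: int = 6
    n_participants: int = 5
    plots_per_locality: Mapping[str, int] = field(
        default_factory=lambda: {"Paramera": 11, "SantaCruz": 13}
    )
    plot_radius_m: float = 10.0
    erosion_noise: float = 0.15
    cover_noise: float = 0.15

    def __post_init__(self):
        if abs(sum(self.severity_mixture) - 1.0) > 1e-9:
            raise ValueError("severity_mixture must sum to 1")
        if sum(self.strategy_cover) > 1.0 + 1e-9:
            raise ValueError("strategy_cover fractions must sum to <= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @property
    def extent_m(self) -> tuple[float, float]:
        return (self.n_cols * self.cellsize, self.n_rows * self.cellsize)

    def template(self) -> Raster:
        return Raster(
            data=np.zeros((self.n_rows, self.n_cols)),
            west=self.west,
            north=self.north,
            cellsize=self.cellsize,
        )

    def scar_polygon(self) -> shapely.Geometry:
        w, h = self.extent_m
        cx = self.west + self.scar_center_frac[0] * w
        cy = self.north - h + self.scar_center_frac[1] * h
        ellipse = affinity.scale(
            Point(cx, cy).buffer(1.0, quad_segs=64),
            xfact=self.scar_radii_frac[0] * w,
            yfact=self.scar_radii_frac[1] * h,
        )
        return affinity.rotate(ellipse, self.scar_rotation_deg)


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells)
    span = np.ptp(f)
    return (f - f.min()) / span if span > 0 else np.zeros(shape)


def generate_terrain(scenario: SyntheticScenario) -> Raster:
    """Smoothed random-field DEM with a gentle regional tilt."""
    cs = scenario.dem_cellsize
    nrows = int(round(scenario.n_rows * scenario.cellsize / cs))
    ncols = int(round(scenario.n_cols * scenario.cellsize / cs))
    rng = scenario.rng(_TERRAIN)
    if scenario.relief_amplitude_m == 0:
        z = np.zeros((nrows, ncols))
    else:
        z = scenario.relief_amplitude_m * _smooth_field(
            rng, (nrows, ncols), scenario.terrain_smoothing_m / cs
        )
        # regional tilt so even smooth areas drain somewhere
        yy = np.linspace(0, 1, nrows)[:, None]
        z = z + 0.2 * scenario.relief_amplitude_m * yy
    return Raster(data=z, west=scenario.west, north=scenario.north, cellsize=cs)


def _severity_dnbr_field(
    scenario: SyntheticScenario, scar_mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Target dNBR inside the scar following the severity mixture.

    A smooth random field is rank-sliced into the three class area
    fractions; per-class dNBR values are drawn within the class bands.
    """
    shape = scar_mask.shape
    f = _smooth_field(rng, shape, 6.0)
    vals = f[scar_mask]
    order = np.argsort(vals, kind="stable")
    n = vals.size
    p_low, p_mod, _ = scenario.severity_mixture
    n_low = int(round(p_low * n))
    n_mod = int(round(p_mod * n))
    cls = np.empty(n, dtype=int)
    cls[order[:n_low]] = 0
    cls[order[n_low : n_low + n_mod]] = 1
    cls[order[n_low + n_mod :]] = 2
    bands = ((0.12, 0.26), (0.28, 0.64), (0.67, 0.85))
    d = np.empty(n)
    for k, (lo, hi) in enumerate(bands):
        sel = cls == k
        d[sel] = rng.uniform(lo, hi, size=int(sel.sum()))
    out = np.zeros(shape)
    out[scar_mask] = d
    return out


def generate_band_stacks(
    scenario: SyntheticScenario,
) -> tuple[BandStack, BandStack, shapely.Geometry, list[SceneMeta]]:
    """Pre/post reflectance stacks, burn perimeter, and a scene catalog.

    Inside the scar the post-fire NIR drops and SWIR rises so that the
    realized dNBR matches the target severity field; RED/BLUE increase
    slightly with burn intensity so the bare-soil index also responds.
    The catalog contains cloudy decoys inside the initial 30-day buffer
    plus clean scenes that require one buffer expansion on the pre side.
    """
    template = scenario.template()
    rng = scenario.rng(_BANDS)
    shape = template.shape

    def band(base: float, wiggle: float) -> np.ndarray:
        return np.clip(
            base * (1.0 + wiggle * (2 * _smooth_field(rng, shape, 4.0) - 1)), 1e-3, None
        )

    blue = band(0.05, 0.3)
    red = band(0.09, 0.3)
    nir = band(0.42, 0.25)
    swir = band(0.18, 0.25)
    pre = BandStack(
        blue=template.like(blue),
        red=template.like(red),
        nir=template.like(nir),
        swir=template.like(swir),
    )

    scar = scenario.scar_polygon()
    xs, ys = template.center_grids()
    scar_mask = shapely.contains_xy(scar, xs, ys)
    dnbr_target = _severity_dnbr_field(scenario, scar_mask, rng)
    dnbr_target += ~scar_mask * rng.normal(0.0, 0.01, size=shape)

    nbr_pre = (nir - swir) / (nir + swir)
    nbr_post = np.clip(nbr_pre - dnbr_target, -0.95, 0.95)
    total = nir + swir  # keep NIR+SWIR, shift the balance
    nir_post = total * (1 + nbr_post) / 2
    swir_post = total * (1 - nbr_post) / 2
    intensity = np.clip(dnbr_target / 0.85, 0.0, 1.0)
    post = BandStack(
        blue=template.like(np.clip(blue * (1 + 0.5 * intensity), 1e-3, None)),
        red=template.like(np.clip(red * (1 + 0.9 * intensity), 1e-3, None)),
        nir=template.like(np.clip(nir_post, 1e-3, None)),
        swir=template.like(np.clip(swir_post, 1e-3, None)),
    )

    d = dt.timedelta
    catalog = [
        SceneMeta("S2_PRE_CLOUDY", scenario.fire_start - d(days=18), 46.0),
        SceneMeta("S2_PRE_CLEAN", scenario.fire_start - d(days=40), 3.5),
        SceneMeta("S2_POST_CLOUDY", scenario.fire_end + d(days=6), 62.0),
        SceneMeta("S2_POST_CLEAN", scenario.fire_end + d(days=12), 4.0),
    ]
    return pre, post, scar, catalog


def _tessellation(scenario: SyntheticScenario) -> list[tuple[str, shapely.Geometry]]:
    w, h = scenario.extent_m
    tiles = []
    dx = w / scenario.n_tile_cols
    dy = h / scenario.n_tile_rows
    south = scenario.north - h
    for r in range(scenario.n_tile_rows):
        for c in range(scenario.n_tile_cols):
            tiles.append(
                (
                    f"poly_{r}{c}",
                    shapely.box(
                        scenario.west + c * dx,
                        south + r * dy,
                        scenario.west + (c + 1) * dx,
                        south + (r + 1) * dy,
                    ),
                )
            )
    return tiles


def generate_vegetation_and_history(
    scenario: SyntheticScenario,
) -> tuple[
    list[VegetationPolygon],
    Raster,
    Raster,
    list[tuple[shapely.Geometry, int]],
]:
    """Vegetation polygons, K and aridity rasters, historical perimeters."""
    rng = scenario.rng(_VEG)
    mix = np.asarray(scenario.strategy_cover, dtype=float)
    total_cover = float(mix.sum())
    polygons: list[VegetationPolygon] = []
    for pid, geom in _tessellation(scenario):
        # per-strategy covers: Dirichlet around the configured mix so the
        # scenario's mean covers are reproduced across polygons
        pos = mix > 0
        covers = np.zeros(3)
        if pos.sum() == 1:
            covers[pos] = total_cover
        elif pos.any():
            shares = rng.dirichlet(scenario.cover_concentration * mix[pos])
            covers[pos] = total_cover * shares
        r_cov, pf_cov, s_cov = covers
        trees: list[SpeciesRecord] = []
        shrub = grass = None
        if r_cov > 0:
            sp = SPECIES_POOL["resprouter"]
            trees.append(
                SpeciesRecord(sp[rng.integers(len(sp))], "tree", 0.7 * r_cov, "resprouter")
            )
            shrub = SpeciesRecord(sp[rng.integers(len(sp))], "shrub", 0.3 * r_cov, "resprouter")
        if pf_cov > 0:
            sp = SPECIES_POOL["postfire_seeder"]
            trees.append(
                SpeciesRecord(sp[rng.integers(len(sp))], "tree", pf_cov, "postfire_seeder")
            )
        if s_cov > 0:
            sp = SPECIES_POOL["seeder"]
            grass = SpeciesRecord(sp[rng.integers(len(sp))], "grass", s_cov, "seeder")
        polygons.append(
            VegetationPolygon(
                polygon_id=pid,
                geometry=geom,
                tree_records=trees,
                shrub_record=shrub,
                grass_record=grass,
            )
        )

    template = scenario.template()
    k_rng = scenario.rng(_KFACT)
    k = template.like(0.05 + 0.50 * _smooth_field(k_rng, template.shape, 6.0))
    a_rng = scenario.rng(_ARID)
    xx = np.linspace(0, 1, template.shape[1])[None, :] * np.ones(template.shape)
    aridity = template.like(
        np.clip(0.10 + 0.55 * xx + 0.10 * (2 * _smooth_field(a_rng, template.shape, 8.0) - 1), 0.02, 0.95)
    )

    # historical perimeters: two recent fires overlapping parts of the scar
    # and one outside the 20-year lookback window
    scar = scenario.scar_polygon()
    cx, cy = scar.centroid.x, scar.centroid.y
    w, h = scenario.extent_m
    hist = [
        (
            affinity.scale(Point(cx - 0.18 * w, cy).buffer(1.0, quad_segs=32),
                           0.18 * w, 0.16 * h),
            scenario.fire_year - 5,
        ),
        (
            affinity.scale(Point(cx + 0.10 * w, cy + 0.08 * h).buffer(1.0, quad_segs=32),
                           0.14 * w, 0.12 * h),
            scenario.fire_year - 12,
        ),
        (
            affinity.scale(Point(cx, cy - 0.15 * h).buffer(1.0, quad_segs=32),
                           0.20 * w, 0.10 * h),
            scenario.fire_year - 30,
        ),
    ]
    return polygons, k, aridity, hist


# ---------------------------------------------------------------------------
# AHP judgments


def _quantize_saaty(v: float) -> float:
    return min(SAATY_SCALE, key=lambda s: abs(s - v))


def _matrix_from_weights(w: np.ndarray, names: Sequence[str]) -> ComparisonMatrix:
    judgments = {}
    for i in range(len(w)):
        for j in range(i + 1, len(w)):
            judgments[(i, j)] = _quantize_saaty(w[i] / w[j])
    return build_comparison_matrix(names, judgments)


def generate_judgments(
    scenario: SyntheticScenario,
) -> tuple[dict[str, ComparisonMatrix], dict[str, ComparisonMatrix]]:
    """Per-participant near-consistent comparison matrices for both models.

    Each participant holds a private priority vector drawn around a common
    prior (participants differ in strength of preference but broadly share
    the importance ordering); judgments are the weight ratios snapped to
    the 1/9..9 scale, so every matrix passes the CR < 0.1 screen.
    """
    rng = scenario.rng(_JUDGE)
    prior = np.array([0.34, 0.24, 0.18, 0.14, 0.10])
    ser, vrp = {}, {}
    for k in range(scenario.n_participants):
        pid = f"participant_{k + 1}"
        ser_w = rng.dirichlet(40.0 * prior)
        vrp_w = rng.dirichlet(40.0 * prior)
        ser[pid] = _matrix_from_weights(ser_w, SER_CRITERIA)
        vrp[pid] = _matrix_from_weights(vrp_w, VRP_CRITERIA)
    return ser, vrp


def averaged_weights(
    matrices: Mapping[str, ComparisonMatrix],
) -> WeightVector:
    return aggregate_weights([derive_weights(m) for m in matrices.values()])


# ---------------------------------------------------------------------------
# Field plots


_SCORE_TO_CODE = {v: k for k, v in EROSION_SCORES.items()}
_SCORES_ASC = tuple(sorted(EROSION_SCORES.values()))


def generate_field_plots(
    scenario: SyntheticScenario,
    true_ser: CompositeIndexMap,
    true_vrp: CompositeIndexMap,
) -> list[FieldPlot]:
    """Field plots whose observations track the true composite indices.

    Plot centers are spread over the within-perimeter SER range, split
    into localities by an east/west divide.  The plot erosion score rises
    stochastically with the sampled true SER (noise level
    ``erosion_noise``); shrub/grass covers fall with the sampled true VRP
    (higher VRP = slower recovery) with noise ``cover_noise``.
    """
    rng = scenario.rng(_PLOTS)
    ser_r = true_ser.index
    xs, ys = ser_r.center_grids()
    finite = np.isfinite(ser_r.data)
    # keep a margin so every plot buffer stays on valid cells
    margin = scenario.plot_radius_m
    inner = (
        finite
        & (xs > ser_r.west + margin)
        & (xs < ser_r.east - margin)
        & (ys > ser_r.south + margin)
        & (ys < ser_r.north - margin)
    )
    cand_x, cand_y = xs[inner], ys[inner]
    cand_ser = ser_r.data[inner]
    if cand_x.size == 0:
        raise ValueError("no valid cells inside the perimeter for plots")

    x_split = np.median(cand_x)
    localities = sorted(scenario.plots_per_locality)
    plots: list[FieldPlot] = []
    counter = 1
    for li, loc in enumerate(localities):
        if li % 2 == 0:
            sel = cand_x <= x_split
        else:
            sel = cand_x > x_split
        lx, ly, lser = cand_x[sel], cand_y[sel], cand_ser[sel]
        if lx.size == 0:
            lx, ly, lser = cand_x, cand_y, cand_ser
        order = np.argsort(lser, kind="stable")
        n = scenario.plots_per_locality[loc]
        picks = order[np.unique(np.linspace(0, lx.size - 1, n).round().astype(int))]
        while picks.size < n:  # tiny candidate pools: repeat extremes
            picks = np.concatenate([picks, picks[: n - picks.size]])
        for px, py in zip(lx[picks], ly[picks]):
            plots.append(
                FieldPlot(
                    plot_id=f"plot_{counter:02d}",
                    x=float(px),
                    y=float(py),
                    locality=loc,
                    impact=str(rng.choice(IMPACTS, p=IMPACT_P)),
                    radius=scenario.plot_radius_m,
                )
            )
            counter += 1

    sampled_ser = fieldval.sample_map_at_plots(true_ser, plots)["value"].to_numpy()
    sampled_vrp = fieldval.sample_map_at_plots(true_vrp, plots)["value"].to_numpy()

    # erosion observations: rank of true SER + noise -> one of the 7 codes
    ranks = pd.Series(sampled_ser).rank(method="average").to_numpy()
    u = (ranks - 0.5) / len(ranks)
    latent = np.clip(u + scenario.erosion_noise * rng.standard_normal(len(u)), 0.0, 1.0)
    n_codes = len(_SCORES_ASC)
    idx = np.minimum((latent * n_codes).astype(int), n_codes - 1)
    # recovery proxy: higher VRP = poorer recovery = less shrub/grass cover
    recovery = np.clip((3.0 - sampled_vrp) / 2.0, 0.0, 1.0)
    shrub = np.clip(
        100 * (0.75 * recovery + scenario.cover_noise * rng.standard_normal(len(u))),
        0.0, 100.0,
    )
    grass = np.clip(
        100 * (0.55 * recovery + scenario.cover_noise * rng.standard_normal(len(u))),
        0.0, 100.0,
    )
    out = []
    for k, p in enumerate(plots):
        score = _SCORES_ASC[idx[k]]
        codes = [_SCORE_TO_CODE[score]]
        # occasionally record an additional milder sign; max-rule unaffected
        if idx[k] > 0 and rng.random() < 0.3:
            codes.append(_SCORE_TO_CODE[_SCORES_ASC[rng.integers(idx[k])]])
        out.append(
            FieldPlot(
                plot_id=p.plot_id,
                x=p.x,
                y=p.y,
                locality=p.locality,
                impact=p.impact,
                erosion_observations=tuple(codes),
                shrub_cover_pct=float(shrub[k]),
                grass_cover_pct=float(grass[k]),
                radius=p.radius,
            )
        )
    return out


IMPACTS = ("none", "compaction", "overgrazing")
IMPACT_P = (0.5, 0.25, 0.25)


# ---------------------------------------------------------------------------
# Full scenario assembly and writing


@dataclass
class ScenarioTruth:
    """In-memory inputs plus the generator's own composite maps."""

    inputs: AssessmentInputs
    ser_matrices: dict[str, ComparisonMatrix]
    vrp_matrices: dict[str, ComparisonMatrix]
    ser_weights: WeightVector
    vrp_weights: WeightVector
    true_ser: CompositeIndexMap
    true_vrp: CompositeIndexMap
    plots: list[FieldPlot]


def build_truth(scenario: SyntheticScenario) -> ScenarioTruth:
    """Generate all inputs and the composite maps they imply (averaged
    participant weights), then condition the field plots on those maps."""
    dem = generate_terrain(scenario)
    pre, post, perimeter, catalog = generate_band_stacks(scenario)
    vegetation, k, aridity, hist = generate_vegetation_and_history(scenario)
    ser_m, vrp_m = generate_judgments(scenario)
    inputs = AssessmentInputs(
        dem=dem,
        pre_stack=pre,
        post_stack=post,
        perimeter=perimeter,
        fire_start=scenario.fire_start,
        fire_end=scenario.fire_end,
        vegetation=vegetation,
        k_factor=k,
        aridity=aridity,
        history_perimeters=hist,
        fire_year=scenario.fire_year,
        catalog=catalog,
    )
    layers = compute_criterion_layers(inputs, target_resolution=scenario.cellsize)
    ser_w = averaged_weights(ser_m)
    vrp_w = averaged_weights(vrp_m)
    true_ser, true_vrp = compute_indices(layers, ser_w, vrp_w)
    plots = generate_field_plots(scenario, true_ser, true_vrp)
    return ScenarioTruth(
        inputs=inputs,
        ser_matrices=ser_m,
        vrp_matrices=vrp_m,
        ser_weights=ser_w,
        vrp_weights=vrp_w,
        true_ser=true_ser,
        true_vrp=true_vrp,
        plots=plots,
    )


def write_scenario_inputs(
    scenario: SyntheticScenario, outdir: str | Path
) -> dict[str, Path]:
    """Write every pipeline input file for the scenario; returns paths."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_truth(scenario)
    inp = truth.inputs
    paths: dict[str, Path] = {}

    paths["dem"] = write_ascii_grid(inp.dem, outdir / "dem.asc")
    for tag, stack in (("pre", inp.pre_stack), ("post", inp.post_stack)):
        for band in ("blue", "red", "nir", "swir"):
            paths[f"{tag}_{band}"] = write_ascii_grid(
                getattr(stack, band), outdir / f"{tag}_{band}.asc"
            )
    paths["k_factor"] = write_ascii_grid(inp.k_factor, outdir / "k_factor.asc")
    paths["aridity"] = write_ascii_grid(inp.aridity, outdir / "aridity.asc")

    from shapely.geometry import mapping as shapely_mapping

    perimeter_fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": shapely_mapping(inp.perimeter),
                "properties": {
                    "fire_start": inp.fire_start.isoformat(),
                    "fire_end": inp.fire_end.isoformat(),
                    "fire_year": inp.fire_year,
                },
            }
        ],
    }
    paths["perimeter"] = outdir / "perimeter.geojson"
    with paths["perimeter"].open("w") as fh:
        json.dump(perimeter_fc, fh, indent=1)

    paths["vegetation"] = write_vegetation_geojson(
        inp.vegetation, outdir / "vegetation.geojson"
    )
    paths["fire_history"] = write_perimeters_geojson(
        inp.history_perimeters, outdir / "fire_history.geojson"
    )
    paths["scene_catalog"] = write_scene_catalog(
        inp.catalog, outdir / "scene_catalog.csv"
    )
    paths["judgments_ser"] = write_judgments_csv(
        truth.ser_matrices, outdir / "judgments_ser.csv"
    )
    paths["judgments_vrp"] = write_judgments_csv(
        truth.vrp_matrices, outdir / "judgments_vrp.csv"
    )
    paths["field_plots"] = write_plots_csv(truth.plots, outdir / "field_plots.csv")
    return paths
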