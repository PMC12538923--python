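"""Non-spectral criterion layers and scoring rules.

Covers terrain derivatives (slope, aspect via Horn's method), linear
threshold normalization of continuous criteria, the discrete 1-3 score
tables (aspect, aridity, regeneration strategy, fire history, severity
for the recovery model), percentage of resprouting species and
regeneration capacity from vegetation polygons, and rasterization of
polygon attributes onto the analysis grid.

Score semantics: for soil erosion all continuous criteria are normalized
to [0, 1] between expert thresholds; for vegetation recovery all
criteria carry discrete scores 1 (least impediment to recovery) to 3
(greatest impediment).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping

from .errors import (
    GridShapeError,
    ScoreLookupError,
    UndefinedRCError,
)
from .raster import Raster

# ---------------------------------------------------------------------------
# Terrain


def derive_slope_aspect(dem: Raster) -> tuple[Raster, Raster]:
    """Slope (percent) and aspect (degrees clockwise from north) by Horn's
    3x3 finite differences.

    Aspect follows the GIS convention: the compass direction of steepest
    descent (the direction the slope *faces*).  Border cells are nodata;
    flat cells have slope 0 and nodata aspect.
    """
    z = dem.data
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise GridShapeError("DEM must be at least 2x2")
    cs = dem.cellsize
    nr, nc = z.shape
    dzdx = np.full(z.shape, np.nan)
    dzdy = np.full(z.shape, np.nan)
    # interior 3x3 windows; rows run north -> south, columns west -> east
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx[1:-1, 1:-1] = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy[1:-1, 1:-1] = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)

    grad = np.hypot(dzdx, dzdy)
    slope_pct = 100.0 * grad
    # downslope direction: opposite of the gradient (steepest ascent) vector
    aspect = (np.degrees(np.arctan2(-dzdx, -dzdy))) % 360.0
    aspect[~(grad > 0)] = np.nan  # flat or nodata
    return dem.like(slope_pct), dem.like(aspect)


ASPECT_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


def aspect_to_sector(aspect_deg):
    """Map aspect degrees to 8 compass sectors; nan -> 'FLAT'.

    Accepts scalars or arrays; arrays return an object array of labels.
    """
    def one(v: float) -> str:
        if not np.isfinite(v):
            return "FLAT"
        k = int(((v % 360.0) + 22.5) // 45.0) % 8
        return ASPECT_SECTORS[k]

    arr = np.asarray(aspect_deg, dtype=float)
    if arr.ndim == 0:
        return one(float(arr))
    return np.vectorize(one, otypes=[object])(arr)


# ---------------------------------------------------------------------------
# Continuous threshold normalization (soil-erosion criteria)


@dataclass(frozen=True)
class ContinuousCriterionSpec:
    """Linear 0-1 rescaling between expert thresholds.

    Values at or below ``min_threshold`` score 0, at or above
    ``max_threshold`` score 1, linear in between.  ``polarity`` records
    whether the criterion adds to or is subtracted from the erosion
    composite.
    """

    name: str
    min_threshold: float
    max_threshold: float
    polarity: str = "adds_to_index"  # or "subtracted"

    def __post_init__(self):
        if not self.min_threshold < self.max_threshold:
            raise ValueError("min_threshold must be < max_threshold")
        if self.polarity not in ("adds_to_index", "subtracted"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


#: Expert thresholds for the soil-erosion criteria.  Slope and resprouter
#: cover are in percent/fraction of their natural units: slope in %,
#: resprouters as a cover fraction saturating at 0.4 (40 % cover).
EROSION_THRESHOLDS: dict[str, ContinuousCriterionSpec] = {
    "fsi": ContinuousCriterionSpec("fsi", 0.1, 0.66),
    "k": ContinuousCriterionSpec("k", 0.0, 0.55),
    "bsi": ContinuousCriterionSpec("bsi", -1.0, 1.0),
    "slope": ContinuousCriterionSpec("slope", 9.0, 80.0),
    "resprouters": ContinuousCriterionSpec("resprouters", 0.0, 0.4, polarity="subtracted"),
}


def normalize_continuous(value, spec: ContinuousCriterionSpec):
    """Clamped linear rescale to [0, 1]; non-finite values propagate."""
    v = np.asarray(value, dtype=float)
    out = np.clip(
        (v - spec.min_threshold) / (spec.max_threshold - spec.min_threshold),
        0.0,
        1.0,
    )
    out = np.where(np.isfinite(v), out, np.nan)
    if out.ndim == 0:
        return float(out) if np.isfinite(out) else float("nan")
    return out


def normalize_raster(raster: Raster, spec: ContinuousCriterionSpec) -> Raster:
    return raster.like(normalize_continuous(raster.data, spec))


# ---------------------------------------------------------------------------
# Discrete score tables (vegetation-recovery criteria)


@dataclass(frozen=True)
class DiscreteScoreTable:
    """Ordered rules mapping categories or numeric intervals to scores 1-3.

    ``categories`` maps labels to scores; ``intervals`` is an ordered list
    of ``(lo, hi, lo_closed, hi_closed, score)`` checked in order.  Either
    (or both, for mixed tables) may be given.
    """

    name: str
    categories: Mapping[str, int] | None = None
    intervals: tuple[tuple[float, float, bool, bool, int], ...] | None = None

    def lookup(self, value) -> int:
        if isinstance(value, str):
            if self.categories is None or value not in self.categories:
                raise ScoreLookupError(f"{self.name}: unknown category {value!r}")
            return int(self.categories[value])
        v = float(value)
        if not math.isfinite(v):
            raise ScoreLookupError(f"{self.name}: non-finite value")
        if self.intervals is None:
            raise ScoreLookupError(f"{self.name}: numeric lookup unsupported")
        for lo, hi, lo_c, hi_c, score in self.intervals:
            above = v > lo or (lo_c and v == lo)
            below = v < hi or (hi_c and v == hi)
            if above and below:
                return int(score)
        raise ScoreLookupError(f"{self.name}: value {v} outside table domain")


INF = float("inf")

#: Insolation penalty by slope orientation (northern hemisphere): shaded
#: north-facing sectors recover fastest, south-facing slowest.  Flat
#: terrain carries no insolation penalty.
ASPECT_SCORES = DiscreteScoreTable(
    "aspect",
    categories={
        "N": 1, "NE": 1, "NW": 1,
        "E": 2, "W": 2, "SE": 2, "SW": 2,
        "S": 3,
        "FLAT": 1,
    },
)

#: Aridity-index bands: wetter climates (AI > 0.5) recover fully and fast.
ARIDITY_SCORES = DiscreteScoreTable(
    "aridity",
    intervals=(
        (0.5, INF, False, False, 1),
        (0.21, 0.5, True, True, 2),
        (-INF, 0.21, False, False, 3),
    ),
)

#: Post-fire regeneration strategy ranks.
STRATEGY_SCORES = DiscreteScoreTable(
    "strategy",
    categories={"resprouter": 1, "postfire_seeder": 2, "seeder": 3},
)

#: Severity score for the recovery model, on the dNBR class boundaries.
#: Applies to burned cells; within-perimeter unburned cells score 1.
SEVERITY_VRP_SCORES = DiscreteScoreTable(
    "severity_vrp",
    intervals=(
        (-INF, 0.27, False, False, 1),
        (0.27, 0.66, True, True, 2),
        (0.66, INF, False, False, 3),
    ),
)

BUILTIN_SCORE_TABLES: dict[str, DiscreteScoreTable] = {
    "aspect": ASPECT_SCORES,
    "aridity": ARIDITY_SCORES,
    "strategy": STRATEGY_SCORES,
    "severity_vrp": SEVERITY_VRP_SCORES,
}


def score_discrete(value, table: DiscreteScoreTable) -> int:
    """Look up the 1-3 score for a category label or numeric value."""
    return table.lookup(value)


def score_raster(raster: Raster, table: DiscreteScoreTable) -> Raster:
    """Apply a numeric-interval score table to a raster; nodata propagates."""
    d = raster.data
    out = np.full(d.shape, np.nan)
    finite = np.isfinite(d)
    if table.intervals is None:
        raise ScoreLookupError(f"{table.name}: numeric lookup unsupported")
    assigned = np.zeros(d.shape, dtype=bool)
    for lo, hi, lo_c, hi_c, score in table.intervals:
        above = (d > lo) | (lo_c & (d == lo))
        below = (d < hi) | (hi_c & (d == hi))
        hit = finite & above & below & ~assigned
        out[hit] = score
        assigned |= hit
    if np.any(finite & ~assigned):
        raise ScoreLookupError(f"{table.name}: values outside table domain")
    return raster.like(out)


def score_aspect_raster(aspect: Raster, table: DiscreteScoreTable = ASPECT_SCORES) -> Raster:
    """Score an aspect raster (degrees) through the sector table."""
    sectors = aspect_to_sector(aspect.data)
    out = np.empty(aspect.shape, dtype=float)
    for lbl, sc in table.categories.items():
        out[sectors == lbl] = sc
    return aspect.like(out)


# ---------------------------------------------------------------------------
# Vegetation polygons: % resprouters and regeneration capacity


STRATA = ("tree", "shrub", "grass")
STRATEGIES = ("resprouter", "postfire_seeder", "seeder")


@dataclass(frozen=True)
class SpeciesRecord:
    species: str
    stratum: str  # tree | shrub | grass
    cover_fraction: float  # of polygon area, 0-1
    strategy: str  # resprouter | postfire_seeder | seeder

    def __post_init__(self):
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.cover_fraction <= 1.0:
            raise ValueError("cover_fraction must be in [0, 1]")


@dataclass
class VegetationPolygon:
    """Forest-map polygon: up to 3 co-dominant tree species plus one shrub
    and one grass record, each with its fractional cover."""

    polygon_id: str
    geometry: shapely.Geometry
    tree_records: list[SpeciesRecord] = field(default_factory=list)
    shrub_record: SpeciesRecord | None = None
    grass_record: SpeciesRecord | None = None

    def __post_init__(self):
        if len(self.tree_records) > 3:
            raise ValueError("at most 3 co-dominant tree species per polygon")
        for rec in self.tree_records:
            if rec.stratum != "tree":
                raise ValueError("tree_records must have stratum 'tree'")
        if self.shrub_record and self.shrub_record.stratum != "shrub":
            raise ValueError("shrub_record must have stratum 'shrub'")
        if self.grass_record and self.grass_record.stratum != "grass":
            raise ValueError("grass_record must have stratum 'grass'")
        total = sum(r.cover_fraction for r in self.records())
        if total > 1.0 + 1e-6:
            raise ValueError(f"cover fractions sum to {total:.4f} > 1")

    def records(self) -> list[SpeciesRecord]:
        recs = list(self.tree_records)
        if self.shrub_record is not None:
            recs.append(self.shrub_record)
        if self.grass_record is not None:
            recs.append(self.grass_record)
        return recs


def percent_resprouters(polygon: VegetationPolygon) -> float:
    """Fraction of polygon area covered by resprouting species."""
    return float(
        sum(r.cover_fraction for r in polygon.records() if r.strategy == "resprouter")
    )


def regeneration_capacity(
    polygon: VegetationPolygon,
    strategy_scores: DiscreteScoreTable = STRATEGY_SCORES,
) -> float:
    """Cover-weighted mean strategy score over all strata, in [1, 3].

    RC = (sum_i DT_i C_i + S C_S + G C_G) / (sum_i C_i + C_S + C_G) with
    DT/S/G the strategy scores of the tree/shrub/grass records and C their
    covers.  Lower RC = better inherent recovery.
    """
    num = 0.0
    den = 0.0
    for rec in polygon.records():
        s = strategy_scores.lookup(rec.strategy)
        num += s * rec.cover_fraction
        den += rec.cover_fraction
    if den <= 0.0:
        raise UndefinedRCError(f"polygon {polygon.polygon_id}: zero total cover")
    return num / den


# ---------------------------------------------------------------------------
# Fire history


@dataclass(frozen=True)
class FireHistoryCell:
    """Fire frequency over the last 20 years + time since the last fire."""

    n_fires_20yr: int
    years_since_last_fire: float  # inf if never burned

    def __post_init__(self):
        if self.n_fires_20yr < 0:
            raise ValueError("n_fires_20yr must be nonnegative")
        if self.years_since_last_fire < 0:
            raise ValueError("years_since_last_fire must be nonnegative")
        if self.n_fires_20yr == 0 and math.isfinite(self.years_since_last_fire):
            raise ValueError("unburned cell must have infinite years_since_last_fire")


def _frequency_subscore(n_fires) -> np.ndarray:
    n = np.asarray(n_fires, dtype=float)
    return np.where(n <= 1, 1, np.where(n == 2, 2, 3)).astype(float)


def _interval_subscore(years) -> np.ndarray:
    y = np.asarray(years, dtype=float)
    return np.where(y > 15, 1, np.where(y >= 10, 2, 3)).astype(float)


def score_fire_history(
    cell: FireHistoryCell,
    combination_matrix: Sequence[Sequence[int]] | None = None,
) -> int:
    """Combined fire-history score 1-3.

    Frequency sub-score: <=1 fire -> 1, 2 fires -> 2, >2 -> 3.  Immaturity
    sub-score from the last-fire interval: >15 y -> 1, 10-15 y -> 2,
    <10 y -> 3.  Default combination is the maximum of the two (either
    hazard alone suffices); an explicit 3x3 ``combination_matrix`` indexed
    ``[freq-1][interval-1]`` overrides it.
    """
    f = int(_frequency_subscore(cell.n_fires_20yr))
    t = int(_interval_subscore(cell.years_since_last_fire))
    if combination_matrix is not None:
        return int(combination_matrix[f - 1][t - 1])
    return max(f, t)


def score_fire_history_rasters(
    n_fires: Raster,
    years_since: Raster,
    combination_matrix: Sequence[Sequence[int]] | None = None,
) -> Raster:
    """Vectorized fire-history scoring; nodata propagates."""
    n_fires.require_same_grid(years_since)
    f = _frequency_subscore(np.nan_to_num(n_fires.data, nan=0.0))
    y = np.where(np.isfinite(years_since.data), years_since.data, np.inf)
    t = _interval_subscore(y)
    if combination_matrix is not None:
        cm = np.asarray(combination_matrix, dtype=float)
        out = cm[f.astype(int) - 1, t.astype(int) - 1]
    else:
        out = np.maximum(f, t)
    out = np.where(np.isfinite(n_fires.data), out, np.nan)
    return n_fires.like(out)


def fire_history_from_perimeters(
    perimeters: Sequence[tuple[shapely.Geometry, int]],
    template: Raster,
    reference_year: int,
    lookback_years: int = 20,
) -> tuple[Raster, Raster]:
    """Per-cell fire count over the lookback window and years since the
    most recent fire (inf where never burned), from historical perimeter
    polygons with their fire years.  Membership by cell center."""
    xs, ys = template.center_grids()
    n = np.zeros(template.shape)
    last_year = np.full(template.shape, -np.inf)
    for geom, year in perimeters:
        if year < reference_year - lookback_years or year > reference_year:
            continue
        inside = shapely.contains_xy(geom, xs, ys)
        n[inside] += 1
        last_year[inside] = np.maximum(last_year[inside], year)
    years_since = np.where(n > 0, reference_year - last_year, np.inf)
    return template.like(n), template.like(years_since)


# ---------------------------------------------------------------------------
# Rasterization and GeoJSON I/O


def rasterize_polygons(
    polygons: Sequence[tuple[shapely.Geometry, float]], template: Raster
) -> Raster:
    """Burn (geometry, value) pairs onto the template grid by cell-center
    membership; later polygons win on overlap; uncovered cells are nodata."""
    xs, ys = template.center_grids()
    out = np.full(template.shape, np.nan)
    for geom, value in polygons:
        inside = shapely.contains_xy(geom, xs, ys)
        out[inside] = value
    return template.like(out)


def read_vegetation_geojson(path: str | Path) -> list[VegetationPolygon]:
    """Read vegetation polygons from a GeoJSON FeatureCollection.

    Each feature carries ``polygon_id`` and a ``species`` list of
    ``{species, stratum, cover, strategy}`` records.
    """
    with Path(path).open() as fh:
        fc = json.load(fh)
    out = []
    for feat in fc["features"]:
        props = feat["properties"]
        trees, shrub, grass = [], None, None
        for rec in props.get("species", []):
            sr = SpeciesRecord(
                species=rec["species"],
                stratum=rec["stratum"],
                cover_fraction=float(rec["cover"]),
                strategy=rec["strategy"],
            )
            if sr.stratum == "tree":
                trees.append(sr)
            elif sr.stratum == "shrub":
                shrub = sr
            else:
                grass = sr
        out.append(
            VegetationPolygon(
                polygon_id=str(props["polygon_id"]),
                geometry=shapely_shape(feat["geometry"]),
                tree_records=trees,
                shrub_record=shrub,
                grass_record=grass,
            )
        )
    return out


def write_vegetation_geojson(
    polygons: Sequence[VegetationPolygon], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = []
    for p in polygons:
        features.append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(p.geometry),
                "properties": {
                    "polygon_id": p.polygon_id,
                    "species": [
                        {
                            "species": r.species,
                            "stratum": r.stratum,
                            "cover": r.cover_fraction,
                            "strategy": r.strategy,
                        }
                        for r in p.records()
                    ],
                },
            }
        )
    with path.open("w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
    return path


def read_perimeters_geojson(path: str | Path) -> list[tuple[shapely.Geometry, int]]:
    """Read fire perimeters with a ``year`` property."""
    with Path(path).open() as fh:
        fc = json.load(fh)
    return [
        (shapely_shape(f["geometry"]), int(f["properties"]["year"]))
        for f in fc["features"]
    ]


def write_perimeters_geojson(
    perimeters: Sequence[tuple[shapely.Geometry, int]], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = [
        {
            "type": "Feature",
            "geometry": shapely_mapping(geom),
            "properties": {"year": int(year)},
        }
        for geom, year in perimeters
    ]
    with path.open("w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
    return path
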