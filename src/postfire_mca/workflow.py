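"""Core assessment workflow: inputs -> criterion layers -> composite maps.

This is the computational spine shared by the command-line pipeline and
by the synthetic-data generator (which uses it to derive the 'true'
index maps that its field-plot observations are conditioned on).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely

from .ahp import WeightVector
from .composite import (
    CompositeIndexMap,
    Layer,
    SER_CRITERIA,
    VRP_CRITERIA,
    align_layers,
    compute_ser,
    compute_vrp,
)
from .criteria import (
    ARIDITY_SCORES,
    ASPECT_SCORES,
    EROSION_THRESHOLDS,
    SEVERITY_VRP_SCORES,
    VegetationPolygon,
    derive_slope_aspect,
    fire_history_from_perimeters,
    normalize_raster,
    percent_resprouters,
    rasterize_polygons,
    regeneration_capacity,
    score_aspect_raster,
    score_fire_history_rasters,
    score_raster,
)
from .raster import Raster
from .spectral import BandStack, SceneMeta, compute_bsi, compute_dnbr, compute_nbr
from .errors import GridShapeError


@dataclass
class AssessmentInputs:
    """Everything the two composite models consume."""

    dem: Raster
    pre_stack: BandStack
    post_stack: BandStack
    perimeter: shapely.Geometry
    fire_start: dt.date
    fire_end: dt.date
    vegetation: list[VegetationPolygon]
    k_factor: Raster
    aridity: Raster
    history_perimeters: list[tuple[shapely.Geometry, int]]
    fire_year: int
    catalog: list[SceneMeta] = field(default_factory=list)


@dataclass
class CriterionLayers:
    """Aligned criterion layers on a common analysis grid.

    Erosion-model layers are [0, 1]; recovery-model layers are 1-3.
    ``mask`` is 1 inside the burned perimeter, 0 outside.
    """

    template: Raster
    mask: Raster
    dnbr: Raster
    # soil erosion (continuous, normalized)
    fsi_norm: Raster
    k_norm: Raster
    bsi_norm: Raster
    pr_norm: Raster
    slope_norm: Raster
    # vegetation recovery (discrete / RC, 1-3)
    rc: Raster
    fsi_score: Raster
    aridity_score: Raster
    aspect_score: Raster
    fire_history_score: Raster

    def ser_layers(self) -> dict[str, Raster]:
        return {
            "fsi": self.fsi_norm,
            "k": self.k_norm,
            "bsi": self.bsi_norm,
            "resprouters": self.pr_norm,
            "slope": self.slope_norm,
        }

    def vrp_layers(self) -> dict[str, Raster]:
        return {
            "rc": self.rc,
            "fsi": self.fsi_score,
            "aridity": self.aridity_score,
            "aspect": self.aspect_score,
            "fire_history": self.fire_history_score,
        }


def compute_criterion_layers(
    inputs: AssessmentInputs,
    target_resolution: float = 10.0,
    erosion_thresholds=EROSION_THRESHOLDS,
    aridity_table=ARIDITY_SCORES,
    aspect_table=ASPECT_SCORES,
    severity_vrp_table=SEVERITY_VRP_SCORES,
    fire_history_matrix: Sequence[Sequence[int]] | None = None,
) -> CriterionLayers:
    """Derive, normalize/score, and co-register all criterion layers."""
    # spectral layers at native band resolution
    pre_nbr = compute_nbr(inputs.pre_stack)
    post_nbr = compute_nbr(inputs.post_stack)
    dnbr = compute_dnbr(pre_nbr, post_nbr)
    bsi = compute_bsi(inputs.post_stack)

    # terrain layers at DEM resolution
    slope_pct, aspect_deg = derive_slope_aspect(inputs.dem)
    aspect_score = score_aspect_raster(aspect_deg, aspect_table)

    aligned = align_layers(
        [
            Layer("dnbr", dnbr),
            Layer("bsi", bsi),
            Layer("k", inputs.k_factor),
            Layer("aridity", inputs.aridity),
            Layer("slope", slope_pct),
            Layer("aspect_score", aspect_score, categorical=True),
        ],
        target_resolution=target_resolution,
    )
    grids = {l.name: l.raster for l in aligned}
    template = grids["dnbr"]

    # polygon-borne layers, rasterized directly on the analysis grid
    pr = rasterize_polygons(
        [(p.geometry, percent_resprouters(p)) for p in inputs.vegetation], template
    )
    rc = rasterize_polygons(
        [(p.geometry, regeneration_capacity(p)) for p in inputs.vegetation], template
    )
    n_fires, years_since = fire_history_from_perimeters(
        inputs.history_perimeters, template, reference_year=inputs.fire_year
    )
    fh_score = score_fire_history_rasters(n_fires, years_since, fire_history_matrix)

    xs, ys = template.center_grids()
    mask = template.like(
        shapely.contains_xy(inputs.perimeter, xs, ys).astype(float)
    )

    return CriterionLayers(
        template=template,
        mask=mask,
        dnbr=grids["dnbr"],
        fsi_norm=normalize_raster(grids["dnbr"], erosion_thresholds["fsi"]),
        k_norm=normalize_raster(grids["k"], erosion_thresholds["k"]),
        bsi_norm=normalize_raster(grids["bsi"], erosion_thresholds["bsi"]),
        pr_norm=normalize_raster(pr, erosion_thresholds["resprouters"]),
        slope_norm=normalize_raster(grids["slope"], erosion_thresholds["slope"]),
        rc=rc,
        fsi_score=score_raster(grids["dnbr"], severity_vrp_table),
        aridity_score=score_raster(grids["aridity"], aridity_table),
        aspect_score=grids["aspect_score"],
        fire_history_score=fh_score,
    )


def compute_indices(
    layers: CriterionLayers,
    ser_weights: WeightVector,
    vrp_weights: WeightVector,
) -> tuple[CompositeIndexMap, CompositeIndexMap]:
    """Both composite maps, masked to the burned perimeter."""
    ser = compute_ser(
        layers.fsi_norm,
        layers.k_norm,
        layers.bsi_norm,
        layers.pr_norm,
        layers.slope_norm,
        ser_weights,
        mask=layers.mask,
    )
    vrp = compute_vrp(
        layers.rc,
        layers.fsi_score,
        layers.aridity_score,
        layers.aspect_score,
        layers.fire_history_score,
        vrp_weights,
        mask=layers.mask,
    )
    return ser, vrp
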