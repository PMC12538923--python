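"""Layer alignment and the two additive composite indices.

The simple additive weighting model combines criterion layers with
AHP-derived weights:

* soil erosion risk, from [0, 1]-normalized layers, with the resprouter
  term subtracted (early resprouting mitigates erosion):
  ``SER = FSI*w_FSI + K*w_K + BSI*w_BSI - PR*w_PR + Slo*w_Slo``
* vegetation recovery potential, from 1-3 scored layers:
  ``VRP = RC*w_RC + FSI*w_FSI + AI*w_AI + Asp*w_Asp + FH*w_FH``

Higher values mean greater erosion risk / greater impediment to
recovery.  Both indices are evaluated inside the burned perimeter only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .ahp import WeightVector
from .errors import DegenerateBandsError, GridShapeError, NoOverlapError
from .raster import Raster

SER_CRITERIA = ("fsi", "k", "bsi", "resprouters", "slope")
VRP_CRITERIA = ("rc", "fsi", "aridity", "aspect", "fire_history")


@dataclass
class Layer:
    """A named criterion layer with its resampling semantics."""

    name: str
    raster: Raster
    categorical: bool = False


@dataclass
class CompositeIndexMap:
    """A composite index raster plus the scheme that produced it."""

    index: Raster
    index_kind: str  # "SER" | "VRP"
    weights: WeightVector
    provenance: list[str] = field(default_factory=list)
    value_range: tuple[float, float] = (0.0, 1.0)


def align_layers(
    layers: Sequence[Layer], target_resolution: float = 10.0
) -> list[Layer]:
    """Resample layers onto a common grid at ``target_resolution``.

    The target extent is the intersection of all layer extents, snapped
    outward-in to whole cells.  Continuous layers are resampled
    bilinearly, categorical/discrete layers by nearest neighbour (so the
    output value set stays within the input's).  Layers already on the
    target grid pass through unchanged.
    """
    if not layers:
        raise ValueError("no layers to align")
    west = max(l.raster.west for l in layers)
    east = min(l.raster.east for l in layers)
    south = max(l.raster.south for l in layers)
    north = min(l.raster.north for l in layers)
    ncols = int(math.floor((east - west) / target_resolution + 1e-9))
    nrows = int(math.floor((north - south) / target_resolution + 1e-9))
    if ncols < 1 or nrows < 1:
        raise NoOverlapError("layer extents do not share a full target cell")
    # anchor the target grid at the intersection's NW corner
    target = Raster(
        data=np.zeros((nrows, ncols)),
        west=west,
        north=north,
        cellsize=target_resolution,
        crs=layers[0].raster.crs,
    )
    out = []
    for layer in layers:
        src = layer.raster
        if src.same_grid(target):
            out.append(Layer(layer.name, src.copy(), layer.categorical))
            continue
        xs = target.x_centers()
        ys = target.y_centers()
        cols = (xs - src.west) / src.cellsize - 0.5
        rows = (src.north - ys) / src.cellsize - 0.5
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        order = 0 if layer.categorical else 1
        resampled = ndimage.map_coordinates(
            src.data, [rr, cc], order=order, mode="nearest"
        )
        # nodata handling: mark cells whose source neighbourhood is nodata
        invalid = ndimage.map_coordinates(
            (~np.isfinite(src.data)).astype(float), [rr, cc], order=order, mode="nearest"
        )
        resampled = np.where(invalid > 0, np.nan, resampled)
        out.append(Layer(layer.name, target.like(resampled), layer.categorical))
    return out


def _weighted_sum(
    grids: Sequence[Raster],
    names: Sequence[str],
    w: WeightVector,
    signs: Sequence[float],
) -> Raster:
    if tuple(w.criteria_names) != tuple(names):
        raise GridShapeError(
            f"weight vector must cover {names} in order, got {w.criteria_names}"
        )
    base = grids[0]
    for g in grids[1:]:
        base.require_same_grid(g)
    acc = np.zeros(base.shape)
    for g, wi, s in zip(grids, w.weights, signs):
        acc = acc + s * wi * g.data
    return base.like(acc)


def _apply_mask(index: Raster, mask: Raster | None) -> Raster:
    if mask is None:
        return index
    index.require_same_grid(mask)
    keep = np.isfinite(mask.data) & (mask.data > 0)
    return index.like(np.where(keep, index.data, np.nan))


def compute_ser(
    fsi_norm: Raster,
    k_norm: Raster,
    bsi_norm: Raster,
    pr_norm: Raster,
    slo_norm: Raster,
    w: WeightVector,
    mask: Raster | None = None,
) -> CompositeIndexMap:
    """Post-fire soil erosion risk composite.

    All inputs are [0, 1]-normalized; the resprouter layer enters with a
    negative sign, so the theoretical range is [-w_PR, 1 - w_PR].
    Negative values are retained.  ``mask`` (burned perimeter, >0 inside)
    restricts the output.
    """
    index = _weighted_sum(
        (fsi_norm, k_norm, bsi_norm, pr_norm, slo_norm),
        SER_CRITERIA,
        w,
        signs=(1, 1, 1, -1, 1),
    )
    w_pr = w["resprouters"]
    return CompositeIndexMap(
        index=_apply_mask(index, mask),
        index_kind="SER",
        weights=w,
        provenance=[f"{n}:[0,1]" for n in SER_CRITERIA],
        value_range=(-w_pr, 1.0 - w_pr),
    )


def compute_vrp(
    rc: Raster,
    fsi_score: Raster,
    ai_score: Raster,
    asp_score: Raster,
    fh_score: Raster,
    w: WeightVector,
    mask: Raster | None = None,
) -> CompositeIndexMap:
    """Post-fire vegetation recovery composite on the 1-3 score scale.

    A convex combination of the five scored layers, so the result lies in
    [1, 3]; higher values indicate slower/poorer expected recovery.
    """
    index = _weighted_sum(
        (rc, fsi_score, ai_score, asp_score, fh_score),
        VRP_CRITERIA,
        w,
        signs=(1, 1, 1, 1, 1),
    )
    return CompositeIndexMap(
        index=_apply_mask(index, mask),
        index_kind="VRP",
        weights=w,
        provenance=[f"{n}:[1,3]" for n in VRP_CRITERIA],
        value_range=(1.0, 3.0),
    )


def classify_index(
    cim: CompositeIndexMap, n_bands: int = 3, method: str = "equal"
) -> Raster:
    """Band a composite index into 1..n_bands (low..high).

    ``equal``: equal-interval bands over the theoretical range.
    ``quantile``: bands with equal cell counts (errors on constant maps).
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    d = cim.index.data
    finite = np.isfinite(d)
    if method == "equal":
        lo, hi = cim.value_range
        edges = np.linspace(lo, hi, n_bands + 1)[1:-1]
    elif method == "quantile":
        vals = d[finite]
        if vals.size == 0 or np.ptp(vals) == 0:
            raise DegenerateBandsError("quantile banding on a constant/empty map")
        edges = np.quantile(vals, np.linspace(0, 1, n_bands + 1)[1:-1])
        if np.unique(edges).size < edges.size:
            raise DegenerateBandsError("quantile edges are not distinct")
    else:
        raise ValueError(f"unknown banding method {method!r}")
    bands = np.full(d.shape, np.nan)
    bands[finite] = 1 + np.searchsorted(edges, d[finite], side="right")
    return cim.index.like(bands)
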