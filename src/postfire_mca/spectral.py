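"""Spectral criterion layers: scene selection, NBR, dNBR, BSI, severity.

Burn severity is mapped with the differenced Normalized Burn Ratio,
dNBR = NBR_pre - NBR_post with NBR = (NIR - SWIR) / (NIR + SWIR),
computed from pre- and post-fire reflectance stacks selected around the
fire dates.  Soil exposure is mapped with the Bare Soil Index, the
normalized difference of (SWIR + RED) against (NIR + BLUE).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GridShapeError, NoSceneError
from .raster import Raster

#: dNBR class boundaries: unburned < 0.1 <= low < 0.27 <= moderate <= 0.66 < high
SEVERITY_BOUNDS = (0.1, 0.27, 0.66)

SEVERITY_CODES = {"unburned": 0, "low": 1, "moderate": 2, "high": 3}
SEVERITY_LABELS = {v: k for k, v in SEVERITY_CODES.items()}


@dataclass(frozen=True)
class SceneMeta:
    """Catalog entry for one satellite acquisition."""

    scene_id: str
    acquisition_date: dt.date
    cloud_fraction: float  # percent, 0-100

    def __post_init__(self):
        if not 0.0 <= self.cloud_fraction <= 100.0:
            raise ValueError("cloud_fraction must be in [0, 100]")


@dataclass
class BandStack:
    """Co-registered BLUE/RED/NIR/SWIR reflectance rasters."""

    blue: Raster
    red: Raster
    nir: Raster
    swir: Raster

    def __post_init__(self):
        for name in ("red", "nir", "swir"):
            band = getattr(self, name)
            self.blue.require_same_grid(band)
            valid = np.isfinite(band.data)
            if np.any(band.data[valid] < 0):
                raise ValueError(f"negative reflectance in band '{name}'")

    @property
    def template(self) -> Raster:
        return self.blue


@dataclass
class SeverityMap:
    """Severity class codes (0..3, nan where dNBR is nodata) + source dNBR."""

    classes: Raster
    dnbr: Raster


def select_scene_pair(
    catalog: list[SceneMeta],
    fire_start: dt.date,
    fire_end: dt.date,
    initial_buffer_days: int = 30,
    cloud_max_pct: float = 10.0,
    buffer_step_days: int = 15,
    max_buffer_days: int = 120,
) -> tuple[list[SceneMeta], list[SceneMeta]]:
    """Select pre- and post-fire scenes, widening the time buffer as needed.

    Starting from ``initial_buffer_days``, the window before ignition and
    after extinction is enlarged by ``buffer_step_days`` until both sides
    contain at least one scene with cloud cover below ``cloud_max_pct``,
    or ``max_buffer_days`` is reached.
    """
    if fire_start > fire_end:
        raise ValueError("fire_start must not be after fire_end")
    clean = [s for s in catalog if s.cloud_fraction < cloud_max_pct]

    def window(buffer_days: int) -> tuple[list[SceneMeta], list[SceneMeta]]:
        delta = dt.timedelta(days=buffer_days)
        pre = [s for s in clean if fire_start - delta <= s.acquisition_date < fire_start]
        post = [s for s in clean if fire_end < s.acquisition_date <= fire_end + delta]
        key = lambda s: (s.acquisition_date, s.scene_id)
        return sorted(pre, key=key), sorted(post, key=key)

    buffer_days = initial_buffer_days
    while True:
        pre, post = window(buffer_days)
        if pre and post:
            return pre, post
        if buffer_days >= max_buffer_days:
            missing = []
            if not pre:
                missing.append("pre-fire")
            if not post:
                missing.append("post-fire")
            raise NoSceneError(
                " and ".join(missing),
                f"no qualifying {' and '.join(missing)} scene(s) with cloud "
                f"< {cloud_max_pct}% within {max_buffer_days} days",
            )
        buffer_days = min(buffer_days + buffer_step_days, max_buffer_days)


def _normalized_difference(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = np.isfinite(num) & np.isfinite(den) & (den != 0)
    out[ok] = num[ok] / den[ok]
    return out


def compute_nbr(stack: BandStack, cloud_mask: np.ndarray | None = None) -> Raster:
    """Normalized Burn Ratio (NIR - SWIR) / (NIR + SWIR) in [-1, 1].

    ``cloud_mask`` (True = cloudy) sets masked cells to nodata.
    """
    nir, swir = stack.nir.data, stack.swir.data
    nbr = _normalized_difference(nir - swir, nir + swir)
    if cloud_mask is not None:
        if cloud_mask.shape != nbr.shape:
            raise GridShapeError("cloud mask shape mismatch")
        nbr = np.where(cloud_mask, np.nan, nbr)
    return stack.template.like(nbr)


def compute_bsi(stack: BandStack, cloud_mask: np.ndarray | None = None) -> Raster:
    """Bare Soil Index: ((SWIR+RED) - (NIR+BLUE)) / ((SWIR+RED) + (NIR+BLUE)).

    Positive over exposed mineral soil, negative over green vegetation;
    bounded in [-1, 1] for nonnegative reflectances.
    """
    a = stack.swir.data + stack.red.data
    b = stack.nir.data + stack.blue.data
    bsi = _normalized_difference(a - b, a + b)
    if cloud_mask is not None:
        if cloud_mask.shape != bsi.shape:
            raise GridShapeError("cloud mask shape mismatch")
        bsi = np.where(cloud_mask, np.nan, bsi)
    return stack.template.like(bsi)


def compute_dnbr(pre_nbr: Raster, post_nbr: Raster) -> Raster:
    """dNBR = NBR_pre - NBR_post; nodata propagates."""
    pre_nbr.require_same_grid(post_nbr)
    return pre_nbr.like(pre_nbr.data - post_nbr.data)


def mosaic(rasters: list[Raster]) -> Raster:
    """Per-pixel mean of valid observations across co-registered rasters."""
    if not rasters:
        raise ValueError("nothing to mosaic")
    for r in rasters[1:]:
        rasters[0].require_same_grid(r)
    stack = np.stack([r.data for r in rasters])
    with np.errstate(invalid="ignore"):
        out = np.nanmean(stack, axis=0)
    return rasters[0].like(out)


def classify_severity(
    dnbr: Raster, bounds: tuple[float, float, float] = SEVERITY_BOUNDS
) -> SeverityMap:
    """Classify dNBR into unburned/low/moderate/high.

    unburned: dNBR < bounds[0]; low: [bounds[0], bounds[1]);
    moderate: [bounds[1], bounds[2]]; high: > bounds[2].
    Every finite value receives exactly one class; nodata stays nodata.
    """
    lo, mid, hi = bounds
    d = dnbr.data
    classes = np.full(d.shape, np.nan)
    finite = np.isfinite(d)
    classes[finite & (d < lo)] = SEVERITY_CODES["unburned"]
    classes[finite & (d >= lo) & (d < mid)] = SEVERITY_CODES["low"]
    classes[finite & (d >= mid) & (d <= hi)] = SEVERITY_CODES["moderate"]
    classes[finite & (d > hi)] = SEVERITY_CODES["high"]
    return SeverityMap(classes=dnbr.like(classes), dnbr=dnbr)


# ---------------------------------------------------------------------------
# Catalog CSV interface

def read_scene_catalog(path: str | Path) -> list[SceneMeta]:
    """Read a scene catalog CSV with columns ``scene_id,date,cloud_pct``."""
    df = pd.read_csv(path)
    return [
        SceneMeta(
            scene_id=str(row["scene_id"]),
            acquisition_date=dt.date.fromisoformat(str(row["date"])),
            cloud_fraction=float(row["cloud_pct"]),
        )
        for _, row in df.iterrows()
    ]


def write_scene_catalog(scenes: list[SceneMeta], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "scene_id": [s.scene_id for s in scenes],
            "date": [s.acquisition_date.isoformat() for s in scenes],
            "cloud_pct": [s.cloud_fraction for s in scenes],
        }
    ).to_csv(path, index=False)
    return path
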