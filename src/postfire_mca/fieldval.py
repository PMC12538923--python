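"""Field-plot validation harness.

Field observations from 10 m-radius circular plots are reduced to two
plot-level quantities: an erosion intensity score (the maximum of the
per-category scores of the erosion types observed) and a height-weighted
vegetation recovery proxy (shrub and grass cover fractions weighted by
typical stratum heights; standing trees are excluded to focus on
early-successional vegetation).  Composite maps are sampled with the
same 10 m buffer around each plot center, and observed-vs-predicted
agreement is summarized with Spearman rank correlation, OLS regression,
and one-way ANOVA by locality and by human/animal impact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composite import CompositeIndexMap
from .errors import VocabularyError
from .raster import Raster

#: Erosion-type intensity scores; the plot score is the maximum observed.
EROSION_SCORES: dict[str, float] = {
    "NE": 0.0,   # no erosion
    "EDD": 0.2,  # weak diffuse (sheet) erosion
    "EDF": 0.4,  # strong diffuse erosion
    "EO": 0.5,   # wind erosion
    "XDD": 0.6,  # weak rill erosion
    "XDF": 0.8,  # strong rill erosion
    "ESF": 0.9,  # collapses / mass movement
}

#: Average stratum heights (m) used to weight cover estimates.
SHRUB_HEIGHT_M = 1.20
GRASS_HEIGHT_M = 0.10

IMPACT_CATEGORIES = ("compaction", "overgrazing", "none")


@dataclass
class FieldPlot:
    plot_id: str
    x: float
    y: float
    locality: str
    impact: str = "none"
    erosion_observations: tuple[str, ...] = ("NE",)
    shrub_cover_pct: float = 0.0
    grass_cover_pct: float = 0.0
    radius: float = 10.0

    def __post_init__(self):
        if not self.erosion_observations:
            raise ValueError("erosion_observations must be nonempty (use NE)")
        for code in self.erosion_observations:
            if code not in EROSION_SCORES:
                raise VocabularyError(f"unknown erosion code {code!r}")
        for v in (self.shrub_cover_pct, self.grass_cover_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError("cover percentages must be in [0, 100]")
        if self.impact not in IMPACT_CATEGORIES:
            raise ValueError(f"unknown impact {self.impact!r}")


def plot_erosion_score(observations: Sequence[str]) -> float:
    """Plot erosion intensity: the highest per-category score observed."""
    if not observations:
        raise VocabularyError("no erosion observations (record NE if none)")
    scores = []
    for code in observations:
        if code not in EROSION_SCORES:
            raise VocabularyError(f"unknown erosion code {code!r}")
        scores.append(EROSION_SCORES[code])
    return max(scores)


def plot_vegetation_recovery(
    shrub_cover_pct: float,
    grass_cover_pct: float,
    shrub_height_m: float = SHRUB_HEIGHT_M,
    grass_height_m: float = GRASS_HEIGHT_M,
) -> float:
    """Height-weighted cover volume proxy (m): h_shrub*C_shrub + h_grass*C_grass."""
    for v in (shrub_cover_pct, grass_cover_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError("cover percentages must be in [0, 100]")
    return shrub_height_m * shrub_cover_pct / 100.0 + grass_height_m * grass_cover_pct / 100.0


def sample_map_at_plots(
    cim: CompositeIndexMap | Raster, plots: Sequence[FieldPlot]
) -> pd.DataFrame:
    """Mean map value within each plot's radius buffer (cell-center membership).

    Returns a frame with ``plot_id, value, n_cells, missing``; plots whose
    buffer contains no valid cell are flagged missing with NaN value.
    """
    raster = cim.index if isinstance(cim, CompositeIndexMap) else cim
    xs, ys = raster.center_grids()
    rows = []
    for p in plots:
        inside = (xs - p.x) ** 2 + (ys - p.y) ** 2 <= p.radius**2
        vals = raster.data[inside]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "plot_id": p.plot_id,
                "value": float(vals.mean()) if vals.size else np.nan,
                "n_cells": int(vals.size),
                "missing": vals.size == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    n_plots: int
    spearman_rho: float
    spearman_p: float
    slope: float
    intercept: float
    r_squared: float
    anova_p: dict[str, float]  # keys: locality_resid, impact_resid, locality_raw, impact_raw
    diagnostics: dict[str, float | bool]


def _anova_p(values: np.ndarray, groups: Sequence[str]) -> float:
    df = pd.DataFrame({"v": values, "g": list(groups)})
    samples = [grp["v"].to_numpy() for _, grp in df.groupby("g") if len(grp) > 1]
    if len(samples) < 2:
        return float("nan")
    return float(stats.f_oneway(*samples).pvalue)


def validate_predictions(
    observed: Sequence[float],
    predicted: Sequence[float],
    plots: Sequence[FieldPlot],
) -> ValidationReport:
    """Observed-vs-predicted statistics over the plot set.

    Spearman uses average ranks for ties.  The OLS fit is
    observed ~ predicted; ANOVA compares both the regression residuals and
    the raw observations across localities and impact categories.
    Constant inputs make the correlation undefined (flagged), while the
    regression is still attempted.
    """
    import statsmodels.api as sm

    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or len(obs) != len(plots):
        raise ValueError("observed, predicted and plots must have equal length")
    keep = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[keep], pred[keep]
    kept_plots = [p for p, k in zip(plots, keep) if k]
    if len(obs) < 3:
        raise ValueError("need at least 3 paired finite values")

    constant = bool(np.ptp(obs) == 0 or np.ptp(pred) == 0)
    if constant:
        rho, rho_p = float("nan"), float("nan")
    else:
        rho, rho_p = stats.spearmanr(obs, pred)

    X = sm.add_constant(pred)
    fit = sm.OLS(obs, X).fit()
    intercept = float(fit.params[0])
    slope = float(fit.params[1]) if len(fit.params) > 1 else float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        r_squared = float(fit.rsquared) if np.isfinite(fit.rsquared) else float("nan")
    resid = np.asarray(fit.resid)

    localities = [p.locality for p in kept_plots]
    impacts = [p.impact for p in kept_plots]
    anova_p = {
        "locality_resid": _anova_p(resid, localities),
        "impact_resid": _anova_p(resid, impacts),
        "locality_raw": _anova_p(obs, localities),
        "impact_raw": _anova_p(obs, impacts),
    }

    # simple diagnostics on residuals
    if np.ptp(resid) > 0 and len(resid) >= 3:
        normality_p = float(stats.shapiro(resid).pvalue)
    else:
        normality_p = float("nan")
    groups = pd.Series(localities)
    resid_groups = [resid[(groups == g).to_numpy()] for g in groups.unique()]
    resid_groups = [g for g in resid_groups if len(g) > 1]
    if len(resid_groups) >= 2:
        homo_p = float(stats.levene(*resid_groups).pvalue)
    else:
        homo_p = float("nan")

    return ValidationReport(
        n_plots=len(obs),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        anova_p=anova_p,
        diagnostics={
            "residual_normality_p": normality_p,
            "homoscedasticity_p": homo_p,
            "constant_input": constant,
        },
    )


# ---------------------------------------------------------------------------
# Plot CSV interface: plot_id,x,y,locality,impact,erosion_codes,shrub_pct,grass_pct


def read_plots_csv(path: str | Path) -> list[FieldPlot]:
    df = pd.read_csv(path)
    plots = []
    for _, row in df.iterrows():
        plots.append(
            FieldPlot(
                plot_id=str(row["plot_id"]),
                x=float(row["x"]),
                y=float(row["y"]),
                locality=str(row["locality"]),
                impact=str(row["impact"]),
                erosion_observations=tuple(str(row["erosion_codes"]).split("|")),
                shrub_cover_pct=float(row["shrub_pct"]),
                grass_cover_pct=float(row["grass_pct"]),
                radius=float(row.get("radius", 10.0)) if "radius" in df.columns else 10.0,
            )
        )
    return plots


def write_plots_csv(plots: Sequence[FieldPlot], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "x": [f"{p.x:.3f}" for p in plots],
            "y": [f"{p.y:.3f}" for p in plots],
            "locality": [p.locality for p in plots],
            "impact": [p.impact for p in plots],
            "erosion_codes": ["|".join(p.erosion_observations) for p in plots],
            "shrub_pct": [f"{p.shrub_cover_pct:.2f}" for p in plots],
            "grass_pct": [f"{p.grass_cover_pct:.2f}" for p in plots],
        }
    ).to_csv(path, index=False)
    return path


def write_validation_report(report: ValidationReport, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        ("n_plots", report.n_plots),
        ("spearman_rho", report.spearman_rho),
        ("spearman_p", report.spearman_p),
        ("slope", report.slope),
        ("intercept", report.intercept),
        ("r_squared", report.r_squared),
    ]
    rows += [(f"anova_p_{k}", v) for k, v in report.anova_p.items()]
    rows += [(f"diag_{k}", v) for k, v in report.diagnostics.items()]
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(
        path, index=False, float_format="%.10g"
    )
    return path


def scatter_plot(
    observed: Sequence[float],
    predicted: Sequence[float],
    plots: Sequence[FieldPlot],
    path: str | Path,
    title: str = "observed vs predicted",
) -> Path:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    localities = sorted({p.locality for p in plots})
    fig, ax = plt.subplots(figsize=(5, 4))
    for loc in localities:
        sel = [i for i, p in enumerate(plots) if p.locality == loc]
        ax.scatter(
            np.asarray(predicted)[sel], np.asarray(observed)[sel], label=loc, s=25
        )
    ax.set_xlabel("predicted (map)")
    ax.set_ylabel("observed (field)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
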