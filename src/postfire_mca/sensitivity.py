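"""Monte-Carlo sensitivity analysis of the AHP weighting schemes.

Each replicate perturbs every nominal weight independently and uniformly
within +/- p (fractionally), renormalizes to sum 1, and re-evaluates the
composite model.  Robustness is summarized by (a) the fraction of
replicates preserving the nominal importance ordering and (b) pairwise
"overlap" fractions - how often two criteria swap order - mirroring the
visual overlap of the weight distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ahp import WeightVector
from .composite import CompositeIndexMap
from .raster import Raster

#: Default perturbation levels (fractional +/- ranges).
DEFAULT_P_LEVELS = (0.1, 0.2, 0.3)

#: Pairwise-overlap fraction below which two weight distributions are
#: considered distinguishable.
DEFAULT_OVERLAP_THRESHOLD = 0.25


@dataclass
class SensitivityResult:
    nominal: WeightVector
    perturbation_fraction: float
    n_reps: int
    samples: np.ndarray  # (n_reps, n_criteria), renormalized
    prenorm_samples: np.ndarray  # before renormalization
    rank_preservation_fraction: float
    pair_overlap: dict[tuple[str, str], float]
    index_summaries: np.ndarray | None = None  # mean composite per replicate

    @property
    def criteria_names(self) -> tuple[str, ...]:
        return self.nominal.criteria_names


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def perturb_weights(w: WeightVector, p: float, rng_seed) -> WeightVector:
    """One perturbed weight vector: w_i ~ U[w_i(1-p), w_i(1+p)], renormalized."""
    if not 0.0 <= p < 1.0:
        raise ValueError("p must be in [0, 1); p >= 1 allows nonpositive weights")
    rng = _as_rng(rng_seed)
    raw = w.weights * rng.uniform(1.0 - p, 1.0 + p, size=len(w.weights))
    return WeightVector(w.criteria_names, raw / raw.sum())


def _summarize_index(value) -> float:
    if isinstance(value, CompositeIndexMap):
        data = value.index.data
    elif isinstance(value, Raster):
        data = value.data
    else:
        return float(value)
    finite = np.isfinite(data)
    return float(np.mean(data[finite])) if finite.any() else float("nan")


def run_sensitivity(
    model: Callable[[WeightVector], object] | None,
    w: WeightVector,
    p: float,
    n_reps: int = 1000,
    rng_seed: int | np.random.Generator = 0,
) -> SensitivityResult:
    """Monte-Carlo perturbation study at level ``p``.

    ``model`` maps a weight vector to a composite map (or scalar summary);
    pass ``None`` to study the weights alone.  Reproducible given
    ``rng_seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 0.0 <= p < 1.0:
        raise ValueError("p must be in [0, 1)")
    rng = _as_rng(rng_seed)
    k = len(w.weights)
    factors = rng.uniform(1.0 - p, 1.0 + p, size=(n_reps, k))
    prenorm = w.weights[None, :] * factors
    samples = prenorm / prenorm.sum(axis=1, keepdims=True)

    nominal_order = np.argsort(-w.weights, kind="stable")
    sample_orders = np.argsort(-samples, axis=1, kind="stable")
    preserved = np.all(sample_orders == nominal_order[None, :], axis=1)
    rank_preservation = float(np.mean(preserved))

    names = w.criteria_names
    pair_overlap: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            nominal_sign = np.sign(w.weights[i] - w.weights[j])
            if nominal_sign == 0:
                # nominally tied criteria are never distinguishable
                pair_overlap[(names[i], names[j])] = 1.0
                continue
            diff_sign = np.sign(samples[:, i] - samples[:, j])
            pair_overlap[(names[i], names[j])] = float(
                np.mean(diff_sign != nominal_sign)
            )

    summaries = None
    if model is not None:
        summaries = np.array(
            [
                _summarize_index(model(WeightVector(names, s)))
                for s in samples
            ]
        )
    return SensitivityResult(
        nominal=w,
        perturbation_fraction=p,
        n_reps=n_reps,
        samples=samples,
        prenorm_samples=prenorm,
        rank_preservation_fraction=rank_preservation,
        pair_overlap=pair_overlap,
        index_summaries=summaries,
    )


@dataclass
class StabilityReport:
    levels: tuple[float, ...]
    distinguishable_at: dict[float, bool]
    stable_p: float | None  # largest p with all smaller levels also stable
    overlap_threshold: float


def stability_report(
    results: Mapping[float, SensitivityResult] | Sequence[SensitivityResult],
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> StabilityReport:
    """Largest perturbation level at which every weight pair stays
    distinguishable (pairwise overlap below the threshold).

    The qualifying set is made downward-closed: instability at a lower
    level disqualifies all larger levels.
    """
    if not isinstance(results, Mapping):
        results = {r.perturbation_fraction: r for r in results}
    levels = tuple(sorted(results))
    if not levels:
        raise ValueError("at least one perturbation level required")
    raw = {
        p: all(v < overlap_threshold for v in results[p].pair_overlap.values())
        or not results[p].pair_overlap
        for p in levels
    }
    distinguishable: dict[float, bool] = {}
    ok_so_far = True
    for p in levels:
        ok_so_far = ok_so_far and raw[p]
        distinguishable[p] = ok_so_far
    stable = [p for p in levels if distinguishable[p]]
    return StabilityReport(
        levels=levels,
        distinguishable_at=distinguishable,
        stable_p=max(stable) if stable else None,
        overlap_threshold=overlap_threshold,
    )


# ---------------------------------------------------------------------------
# Export


def samples_to_frame(result: SensitivityResult) -> pd.DataFrame:
    df = pd.DataFrame(result.samples, columns=list(result.criteria_names))
    df.insert(0, "replicate", np.arange(result.n_reps))
    df["p"] = result.perturbation_fraction
    if result.index_summaries is not None:
        df["index_mean"] = result.index_summaries
    return df


def write_sensitivity_csv(
    results: Sequence[SensitivityResult], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.concat([samples_to_frame(r) for r in results], ignore_index=True)
    frame.to_csv(path, index=False, float_format="%.10g")
    return path


def plot_weight_distributions(
    result: SensitivityResult, path: str | Path
) -> Path:
    """Per-criterion sampled-weight density panel (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 4))
    for k, name in enumerate(result.criteria_names):
        ax.hist(
            result.samples[:, k], bins=40, density=True, alpha=0.5, label=name
        )
        ax.axvline(result.nominal.weights[k], ls="--", lw=0.8, color="k")
    ax.set_xlabel("sampled weight")
    ax.set_ylabel("density")
    ax.set_title(
        f"weight distributions at +/-{result.perturbation_fraction:.0%} "
        f"(n={result.n_reps})"
    )
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
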