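"""Analytic Hierarchy Process: comparison matrices, weights, consistency.

The AHP elicits criterion weights from pairwise relative-importance
judgments on the 1-9 scale (with reciprocals for the inverse
comparisons).  Judgments are organized in a positive reciprocal matrix
``A`` with unit diagonal; weights follow from column-normalizing ``A``
and averaging rows, and judgment coherence is screened with the
consistency ratio CR = CI / RI, where CI = (lambda_max - n) / (n - 1)
and RI is Saaty's random index for matrices of size n.  Judgment sets
with CR < 0.1 are conventionally accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CriteriaOrderError,
    IncompleteJudgmentsError,
    JudgmentDomainError,
    UnsupportedMatrixSizeError,
)

#: Saaty random indices for n = 1..10 (index 0 unused placeholder for n=0).
SAATY_RANDOM_INDEX: tuple[float, ...] = (
    0.0, 0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49,
)

#: Admissible judgment values under strict scale validation.
SAATY_SCALE: tuple[float, ...] = tuple(
    [1.0 / k for k in range(9, 1, -1)] + [float(k) for k in range(1, 10)]
)

CONSISTENCY_THRESHOLD = 0.1


@dataclass(frozen=True)
class ComparisonMatrix:
    """Positive reciprocal pairwise-comparison matrix."""

    criteria_names: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self):
        names = tuple(self.criteria_names)
        object.__setattr__(self, "criteria_names", names)
        m = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", m)
        n = len(names)
        if n < 2:
            raise ValueError("at least 2 criteria required")
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
        if np.any(m <= 0) or not np.all(np.isfinite(m)):
            raise JudgmentDomainError("all entries must be positive and finite")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise ValueError("diagonal must be 1")
        if not np.allclose(m * m.T, 1.0, atol=1e-9):
            raise ValueError("matrix must be reciprocal (a_ji == 1/a_ij)")

    @property
    def n(self) -> int:
        return len(self.criteria_names)


@dataclass(frozen=True)
class WeightVector:
    """Normalized criterion weights (sum to 1, order matches names)."""

    criteria_names: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        names = tuple(self.criteria_names)
        object.__setattr__(self, "criteria_names", names)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or len(w) != len(names):
            raise ValueError("weights must be 1-D, one per criterion")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum():.12f}")

    def __getitem__(self, name: str) -> float:
        return float(self.weights[self.criteria_names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {c: float(w) for c, w in zip(self.criteria_names, self.weights)}


@dataclass(frozen=True)
class ConsistencyReport:
    lambda_max: float
    ci: float
    ri: float
    cr: float
    acceptable: bool


def build_comparison_matrix(
    criteria_names: Sequence[str],
    upper_triangle_judgments: Mapping[tuple[int, int], float],
    strict_scale: bool = False,
) -> ComparisonMatrix:
    """Assemble a full reciprocal matrix from upper-triangle judgments.

    ``upper_triangle_judgments`` maps 0-based index pairs ``(i, j)`` with
    ``i < j`` to the relative importance of criterion i over criterion j.
    The lower triangle is filled with reciprocals, the diagonal with 1.
    With ``strict_scale`` every judgment must lie on the discrete 1/9..9
    scale.
    """
    n = len(criteria_names)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in upper_triangle_judgments:
                raise IncompleteJudgmentsError(
                    f"missing judgment for pair ({criteria_names[i]}, {criteria_names[j]})"
                )
            v = float(upper_triangle_judgments[(i, j)])
            if not np.isfinite(v) or v <= 0:
                raise JudgmentDomainError(f"judgment ({i},{j}) = {v} must be positive")
            if strict_scale and not any(abs(v - s) < 1e-9 for s in SAATY_SCALE):
                raise JudgmentDomainError(f"judgment {v} not on the 1/9..9 scale")
            m[i, j] = v
            m[j, i] = 1.0 / v
    return ComparisonMatrix(tuple(criteria_names), m)


def derive_weights(matrix: ComparisonMatrix) -> WeightVector:
    """Weights by column normalization followed by row averaging.

    Each entry is divided by its column sum (N_ij = a_ij / sum_i a_ij) and
    the weight of criterion i is the mean of row i of N.  For a perfectly
    consistent matrix this recovers the generating weight vector exactly.
    """
    a = matrix.entries
    normalized = a / a.sum(axis=0, keepdims=True)
    w = normalized.mean(axis=1)
    w = w / w.sum()  # absorb rounding; analytically already 1
    return WeightVector(matrix.criteria_names, w)


def principal_eigenvalue(matrix: ComparisonMatrix) -> float:
    """Dominant eigenvalue of the comparison matrix (Perron root)."""
    eigvals = np.linalg.eigvals(matrix.entries)
    return float(np.max(eigvals.real))


def consistency_ratio(
    matrix: ComparisonMatrix,
    random_index: Sequence[float] = SAATY_RANDOM_INDEX,
    threshold: float = CONSISTENCY_THRESHOLD,
) -> ConsistencyReport:
    """Consistency report: lambda_max, CI, RI, CR and acceptability.

    For n <= 2 a reciprocal matrix is always consistent, so CR is defined
    as 0 and the judgments are acceptable.
    """
    n = matrix.n
    lam = principal_eigenvalue(matrix)
    if n <= 2:
        return ConsistencyReport(lambda_max=lam, ci=0.0, ri=0.0, cr=0.0, acceptable=True)
    if n >= len(random_index):
        raise UnsupportedMatrixSizeError(
            f"no random index for n={n} (table covers up to n={len(random_index) - 1})"
        )
    ri = float(random_index[n])
    ci = (lam - n) / (n - 1)
    cr = ci / ri
    return ConsistencyReport(
        lambda_max=lam, ci=ci, ri=ri, cr=cr, acceptable=bool(cr < threshold)
    )


def aggregate_weights(participant_weights: Sequence[WeightVector]) -> WeightVector:
    """Arithmetic mean of participant weight vectors, renormalized.

    Averaging individual weight vectors gives every participant equal say
    in the final ('democratic') weighting scheme.
    """
    if len(participant_weights) == 0:
        raise ValueError("at least one participant required")
    names = participant_weights[0].criteria_names
    for wv in participant_weights[1:]:
        if wv.criteria_names != names:
            raise CriteriaOrderError(
                f"criteria mismatch: {wv.criteria_names} vs {names}"
            )
    mean = np.mean([wv.weights for wv in participant_weights], axis=0)
    return WeightVector(names, mean / mean.sum())


def rank_alternatives(w: WeightVector, scores: np.ndarray) -> np.ndarray:
    """Composite score per alternative: W^T X.

    ``scores`` has one row per criterion (in the weight order) and one
    column per alternative.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(w.weights):
        raise ValueError(
            f"scores must be ({len(w.weights)}, n_alternatives), got {x.shape}"
        )
    return w.weights @ x


# ---------------------------------------------------------------------------
# CSV interfaces

def read_judgments_csv(
    path: str | Path, criteria_names: Sequence[str] | None = None
) -> dict[str, ComparisonMatrix]:
    """Read long-format judgments: ``criterion_a,criterion_b,value,participant``.

    Returns one comparison matrix per participant.  When
    ``criteria_names`` is omitted the order of first appearance in the
    ``criterion_a``/``criterion_b`` columns is used.
    """
    df = pd.read_csv(path)
    required = {"criterion_a", "criterion_b", "value", "participant"}
    if not required.issubset(df.columns):
        raise ValueError(f"judgments CSV must have columns {sorted(required)}")
    if criteria_names is None:
        seen: list[str] = []
        for col in ("criterion_a", "criterion_b"):
            for c in df[col]:
                if c not in seen:
                    seen.append(c)
        criteria_names = seen
    index = {c: k for k, c in enumerate(criteria_names)}
    out: dict[str, ComparisonMatrix] = {}
    for pid, grp in df.groupby("participant", sort=True):
        judgments: dict[tuple[int, int], float] = {}
        for _, row in grp.iterrows():
            i, j = index[row["criterion_a"]], index[row["criterion_b"]]
            if i == j:
                continue
            if i > j:
                i, j = j, i
                v = 1.0 / float(row["value"])
            else:
                v = float(row["value"])
            judgments[(i, j)] = v
        out[str(pid)] = build_comparison_matrix(criteria_names, judgments)
    return out


def write_judgments_csv(
    matrices: Mapping[str, ComparisonMatrix], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid in sorted(matrices):
        m = matrices[pid]
        for i in range(m.n):
            for j in range(i + 1, m.n):
                rows.append(
                    {
                        "criterion_a": m.criteria_names[i],
                        "criterion_b": m.criteria_names[j],
                        "value": f"{m.entries[i, j]:.10g}",
                        "participant": pid,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_weights_csv(path: str | Path) -> dict[str, WeightVector]:
    """Read ``criterion,weight,participant`` CSV into weight vectors."""
    df = pd.read_csv(path)
    out: dict[str, WeightVector] = {}
    for pid, grp in df.groupby("participant", sort=True):
        w = grp["weight"].to_numpy(dtype=float)
        out[str(pid)] = WeightVector(tuple(grp["criterion"]), w / w.sum())
    return out


def write_weights_csv(
    weight_vectors: Mapping[str, WeightVector], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid in sorted(weight_vectors):
        wv = weight_vectors[pid]
        for c, w in zip(wv.criteria_names, wv.weights):
            rows.append(
                {"criterion": c, "weight": f"{w:.12g}", "participant": pid}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
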