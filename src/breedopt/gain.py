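"""Genetic gain per selection path and per year.

Under the optimum index the gain of a path is the expected aggregate
genotype of the individuals surviving *all* used stages jointly,
ΔG_j = z_j·σ_a, computed from the truncated multivariate normal of the
stage indices and the aggregate genotype.  Under decorrelated indices the
stages are independent and the gain is a sum of univariate intensities,
ΔG_j = Σ_i i(p_i)·σ_i, with σ_i the covariance of the standardised stage
index with the aggregate genotype.

Annual genetic gain follows the Rendel–Robertson four-pathway model:
ΔG_a = Σ_j ΔG_j / Σ_j L_j, with generation intervals L_j in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decorrelate import dsi_stage_accuracies
from .index_engine import Trait
from .trunc_mvn import (
    TruncationProblem,
    collapse_duplicate_stages,
    selected_mean,
    univariate_intensity,
)

__all__ = [
    "PathSpec",
    "GainResult",
    "nested_correlation_with_h",
    "gain_osi",
    "gain_dsi",
    "annual_gain",
]

PATHS = ("SS", "SD", "DS", "DD")
STAGE_ORDER = ("PED", "GS", "PPT")


@dataclass(frozen=True)
class PathSpec:
    """Structure of one selection path.

    ``L_by_terminal_stage`` maps each available stage to the generation
    interval (months) realised when that stage is the last one used —
    selected parents breed as soon as their final selection decision falls.
    """

    path_id: str
    n_candidates: int
    n_selected: int
    available_stages: tuple[str, ...]
    L_by_terminal_stage: dict[str, float]

    def __post_init__(self) -> None:
        if self.path_id not in PATHS:
            raise ValueError(f"unknown path {self.path_id!r}")
        if self.n_selected > self.n_candidates:
            raise ValueError("n_selected cannot exceed n_candidates")
        for s in self.available_stages:
            if s not in STAGE_ORDER:
                raise ValueError(f"unknown stage {s!r}")
            if s not in self.L_by_terminal_stage:
                raise ValueError(f"missing generation interval for stage {s!r}")
        if any(L <= 0 for L in self.L_by_terminal_stage.values()):
            raise ValueError("generation intervals must be positive")

    @property
    def selected_fraction(self) -> float:
        return self.n_selected / self.n_candidates


@dataclass(frozen=True)
class GainResult:
    """Per-path gains (kg), generation intervals (months) and annual gain."""

    delta_g_by_path: dict[str, float]
    L_by_path: dict[str, float]
    delta_g_a: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.delta_g_a is None:
            object.__setattr__(
                self,
                "delta_g_a",
                annual_gain(self.delta_g_by_path, self.L_by_path),
            )


def nested_correlation_with_h(accuracies: np.ndarray) -> np.ndarray:
    """Correlation matrix of nested optimum stage indices plus the aggregate
    genotype (last variable).

    For best linear predictors on nested source sets cov(I_i, I_j) equals
    cov(I_i, H), hence corr(I_i, I_j) = acc_i/acc_j for i < j and
    corr(I_i, H) = acc_i.
    """
    a = np.asarray(accuracies, dtype=float)
    if np.any(a <= 0) or np.any(a > 1):
        raise ValueError("accuracies must be in (0, 1]")
    if np.any(np.diff(a) < 0):
        raise ValueError("nested accuracies must be non-decreasing")
    m = len(a)
    R = np.eye(m + 1)
    for i in range(m):
        for j in range(i + 1, m):
            R[i, j] = R[j, i] = a[i] / a[j]
        R[i, m] = R[m, i] = a[i]
    return R


def gain_osi(
    proportions: np.ndarray,
    accuracies: np.ndarray,
    trait: Trait,
) -> float:
    """Path gain ΔG_j (kg) under optimum indices.

    ``accuracies`` are the cumulative optimum-index accuracies of the used
    stages (nested source sets, non-decreasing); ``proportions`` the
    per-stage selected proportions.  Stages with p = 1 contribute no
    truncation; stages whose index duplicates the previous one are merged
    before integration.
    """
    p = np.asarray(proportions, dtype=float)
    a = np.asarray(accuracies, dtype=float)
    if p.shape != a.shape:
        raise ValueError("proportions and accuracies must align")
    keep = p < 1.0
    if not np.any(keep):
        return 0.0
    a, p = collapse_duplicate_stages(a[keep], p[keep])
    R = nested_correlation_with_h(a)
    problem = TruncationProblem.solve(R, p)
    return selected_mean(problem, trait.sigma_a)


def gain_dsi(
    proportions: np.ndarray,
    accuracies: np.ndarray,
    trait: Trait,
) -> float:
    """Path gain ΔG_j (kg) under decorrelated indices:
    Σ_i i(p_i)·σ_i with σ_i = acc_i^{DSI}·σ_a from the orthogonal
    decomposition of the cumulative optimum-index accuracies."""
    p = np.asarray(proportions, dtype=float)
    a = np.asarray(accuracies, dtype=float)
    if p.shape != a.shape:
        raise ValueError("proportions and accuracies must align")
    keep = p < 1.0
    if not np.any(keep):
        return 0.0
    a, p = collapse_duplicate_stages(a[keep], p[keep])
    sig = dsi_stage_accuracies(a) * trait.sigma_a
    return float(sum(univariate_intensity(pi) * s for pi, s in zip(p, sig)))


def annual_gain(delta_g_by_path: dict[str, float], L_by_path: dict[str, float]) -> float:
    """ΔG_a = Σ_j ΔG_j / Σ_j L_j with L in months converted to years.

    All four pathways enter the denominator, including the unselected
    dam-to-dam path (its gain is zero but its generation interval is not).
    """
    if set(delta_g_by_path) != set(L_by_path):
        raise ValueError("paths of gains and intervals must match")
    total_L_years = sum(L_by_path.values()) / 12.0
    if total_L_years <= 0:
        raise ValueError("total generation interval must be positive")
    return sum(delta_g_by_path.values()) / total_L_years
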