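"""Xu–Muir decorrelated selection indices (DSI).

At stage i the DSI weight vector maximises the covariance of the index with
the aggregate genotype subject to (a) unit index variance (b'Pb = 1) and
(b) zero covariance with every earlier stage's index.  With nested source
sets this is exactly the normalised residual of the stage's optimum index
after projecting out the previous stage indices in the P inner product —
the construction used here, which is numerically equivalent to solving the
constrained system by Lagrange multipliers but stabler.

Consequences exploited throughout the package: stage-1 DSI equals the
stage-1 optimum index up to scale, and for nested sets the squared stage
accuracies add up to the squared combined optimum-index accuracy
(orthogonal decomposition of the best linear predictor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .index_engine import IndexMatrices, Trait

__all__ = [
    "DsiStageIndex",
    "DegenerateStageError",
    "dsi_weights",
    "dsi_accuracy",
    "dsi_stage_accuracies",
]

#: residual variance below which a stage adds no independent information
DEGENERACY_TOL = 1e-10


class DegenerateStageError(ValueError):
    """The stage adds no information independent of previous stages."""


@dataclass(frozen=True)
class DsiStageIndex:
    """A decorrelated stage index.

    b satisfies b'Pb = 1 and b'P c = 0 for every previous stage weight
    vector c (columns of B_prev, zero-padded to the current dimension).
    cov_H is the covariance of the standardised index with the aggregate
    genotype (kg) — the σ_i entering the decorrelated gain formula.
    """

    b: np.ndarray
    variance: float
    cov_H: float
    accuracy: float
    B_prev: np.ndarray
    stage_id: str = ""

    def __post_init__(self) -> None:
        if abs(self.variance - 1.0) > 1e-9:
            raise ValueError("DSI index variance must be 1 (b'Pb = 1)")
        if not (-1e-9 <= self.accuracy <= 1.0 + 1e-9):
            raise ValueError(f"accuracy {self.accuracy} outside [0, 1]")


def _pad(v: np.ndarray, dim: int) -> np.ndarray:
    out = np.zeros(dim)
    out[: len(v)] = v
    return out


def dsi_weights(
    m: IndexMatrices,
    prev: list[DsiStageIndex],
    trait: Trait,
    stage_id: str = "",
) -> DsiStageIndex:
    """Decorrelated index on the sources of ``m`` given earlier stage indices.

    ``prev`` must be built on nested subsets of the sources in ``m`` (their
    weight vectors are zero-padded).  Raises :class:`DegenerateStageError`
    when the new sources add no information independent of the earlier
    stages.
    """
    P, G = m.P, m.G
    dim = m.dim
    b_osi = np.linalg.solve(P, G)
    basis = [_pad(d.b, dim) for d in prev]
    b_res = b_osi.copy()
    # previous DSI vectors are P-orthonormal, so plain projection suffices
    for c in basis:
        b_res -= (b_osi @ P @ c) * c
    var_res = float(b_res @ P @ b_res)
    if var_res < DEGENERACY_TOL:
        raise DegenerateStageError(
            f"degenerate stage: residual variance {var_res:.3e} after projecting "
            f"out {len(prev)} previous stage(s)"
        )
    b = b_res / math.sqrt(var_res)
    cov_h = float(b @ G)
    acc = cov_h / trait.sigma_a
    B_prev = np.column_stack(basis) if basis else np.zeros((dim, 0))
    return DsiStageIndex(
        b=b,
        variance=float(b @ P @ b),
        cov_H=cov_h,
        accuracy=min(max(acc, 0.0), 1.0),
        B_prev=B_prev,
        stage_id=stage_id,
    )


def dsi_accuracy(d: DsiStageIndex, trait: Trait) -> float:
    """Accuracy of a decorrelated stage index: cov_H / (sd(index)·σ_a),
    with sd(index) = 1 by the unit-variance constraint."""
    return d.cov_H / (math.sqrt(d.variance) * trait.sigma_a)


def dsi_stage_accuracies(cumulative_accuracies: np.ndarray) -> np.ndarray:
    """Decorrelated stage accuracies implied by cumulative optimum-index
    accuracies over nested stage source sets.

    The orthogonal decomposition gives acc_1 = a_1 and
    acc_i = sqrt(a_i² − a_{i−1}²); used as the fast path inside the grid
    search (the explicit projection in :func:`dsi_weights` is the reference
    construction and is tested against this identity).
    """
    a = np.asarray(cumulative_accuracies, dtype=float)
    if np.any(np.diff(a) < -1e-9):
        raise ValueError("cumulative accuracies must be non-decreasing")
    out = np.empty_like(a)
    out[0] = a[0]
    if len(a) > 1:
        out[1:] = np.sqrt(np.clip(a[1:] ** 2 - a[:-1] ** 2, 0.0, None))
    return out
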