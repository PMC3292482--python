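"""Truncation-selection numerics.

Three primitives drive every genetic-gain prediction in the package:

* ``rect_prob`` — the probability that a zero-mean multivariate normal with
  correlation matrix R exceeds a vector of lower bounds in every coordinate
  (a rectangle/orthant probability), computed by Genz's sequential
  conditioning transform with tensor-product Gauss–Legendre quadrature.
  The implementation is fully deterministic, unlike randomised quasi-Monte
  Carlo integrators, which matters for reproducible grid searches.
* ``solve_thresholds`` — sequential truncation points: t_i is the root of
  P(I_1>t_1, …, I_i>t_i) = Π p_k, found by Brent's method on the monotone
  map t_i ↦ joint probability.
* ``selected_mean`` — the expected aggregate genotype among individuals
  surviving all stages, via the Tallis first-moment formula for a truncated
  multivariate normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import norm

__all__ = [
    "TruncationProblem",
    "rect_prob",
    "solve_thresholds",
    "selected_mean",
    "univariate_intensity",
    "collapse_duplicate_stages",
]

#: standardized bracket for threshold root-finding
_T_MIN, _T_MAX = -9.0, 9.0

#: Gauss–Legendre nodes per transformed dimension, by problem dimension.
#: dim-1 integrals are closed form; the tensor grid has nodes**(dim-1) points.
_GL_NODES = {2: 96, 3: 64, 4: 32, 5: 14, 6: 10, 7: 7}

_gl_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_rule(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre rule mapped to (0, 1)."""
    if n not in _gl_cache:
        x, w = np.polynomial.legendre.leggauss(n)
        _gl_cache[n] = ((x + 1.0) / 2.0, w / 2.0)
    return _gl_cache[n]


def _validate_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    eig = np.linalg.eigvalsh(R)
    if eig[0] < -1e-8:
        raise ValueError(f"correlation matrix not PSD (min eigenvalue {eig[0]:.3e})")
    return R


def rect_prob(R: np.ndarray, lower: np.ndarray) -> float:
    """P(X_i > lower_i for all i) for X ~ N(0, R).

    Coordinates with lower = −inf are marginalised out.  Accuracy is ~1e-8
    for dimensions up to 4 and ~1e-6 beyond; everything is deterministic.
    """
    R = _validate_corr(R)
    lower = np.asarray(lower, dtype=float)
    if lower.shape != (R.shape[0],):
        raise ValueError("lower must have one bound per variable")
    active = np.isfinite(lower)
    if np.any(lower[~np.isfinite(lower)] > 0):  # +inf bound → empty rectangle
        return 0.0
    if not np.any(active):
        return 1.0
    R = R[np.ix_(active, active)]
    a = lower[active]
    m = len(a)
    if m == 1:
        return float(ndtr(-a[0]))
    # order variables by increasing marginal exceedance (most constraining last)
    order = np.argsort(ndtr(-a))[::-1]
    R = R[np.ix_(order, order)]
    a = a[order]
    try:
        C = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        # PSD but rank-deficient: tiny ridge, renormalised
        Rj = R + 1e-10 * np.eye(m)
        d = np.sqrt(np.diag(Rj))
        C = np.linalg.cholesky(Rj / np.outer(d, d))
    nodes = _GL_NODES.get(m, 5)
    x1, w1 = _gl_rule(nodes)
    # tensor grid over the m-1 transformed variables
    grids = np.meshgrid(*([x1] * (m - 1)), indexing="ij")
    W = np.ones(grids[0].size)
    for g in np.meshgrid(*([w1] * (m - 1)), indexing="ij"):
        W = W * g.ravel()
    U = [g.ravel() for g in grids]

    d1 = ndtr(a[0] / C[0, 0])
    f = np.full(U[0].shape, 1.0 - d1)
    y = np.empty((m - 1, U[0].size))
    # y_i = Phi^{-1}(d_i + u_i (1 - d_i)): sample of Z_i conditional on survival
    y[0] = ndtri(np.clip(d1 + U[0] * (1.0 - d1), 1e-16, 1 - 1e-16))
    for i in range(1, m):
        t = (a[i] - C[i, :i] @ y[:i]) / C[i, i]
        di = ndtr(t)
        f *= 1.0 - di
        if i < m - 1:
            y[i] = ndtri(np.clip(di + U[i] * (1.0 - di), 1e-16, 1 - 1e-16))
    return float(np.clip(W @ f, 0.0, 1.0))


def _conditional_rect(R: np.ndarray, lower: np.ndarray, k: int) -> float:
    """P(X_j > lower_j for j ≠ k | X_k = lower_k) under N(0, R)."""
    m = R.shape[0]
    if m == 1:
        return 1.0
    others = [j for j in range(m) if j != k]
    rk = R[others, k]
    denom = np.sqrt(np.clip(1.0 - rk**2, 1e-14, None))
    lo = (lower[others] - rk * lower[k]) / denom
    sub = R[np.ix_(others, others)]
    Rc = (sub - np.outer(rk, rk)) / np.outer(denom, denom)
    np.fill_diagonal(Rc, 1.0)
    return rect_prob(Rc, lo)


def solve_thresholds(R: np.ndarray, proportions: np.ndarray) -> np.ndarray:
    """Sequential truncation points for given per-stage selected proportions.

    t_i satisfies P(I_1 > t_1, …, I_i > t_i) = Π_{k≤i} p_k, solved stage by
    stage with a bracket-safeguarded Newton iteration on the monotone map
    t_i ↦ joint probability (Brent bisection as fallback); the derivative
    −φ(t_i)·Φ_{i−1}(· | I_i = t_i) is available in closed form from the
    same conditioning machinery.  p_i = 1 yields t_i = −inf (stage unused).
    """
    R = _validate_corr(R)
    p = np.asarray(proportions, dtype=float)
    if p.shape != (R.shape[0],):
        raise ValueError("one proportion per stage required")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("proportions must be in (0, 1]")
    m = len(p)
    t = np.full(m, -np.inf)
    target = 1.0
    for i in range(m):
        target *= p[i]
        if p[i] >= 1.0:
            continue
        if i == 0 or not np.any(np.isfinite(t[:i])):
            t[i] = norm.isf(target)
            continue
        Ri = R[: i + 1, : i + 1]

        def joint(ti: float) -> float:
            lo = t[: i + 1].copy()
            lo[i] = ti
            return rect_prob(Ri, lo) - target

        lo_b, hi_b = _T_MIN, _T_MAX
        f_lo, f_hi = joint(lo_b), joint(hi_b)
        if f_lo < 0.0 or f_hi > 0.0:
            raise ValueError(
                f"no bracket for stage {i}: joint({_T_MIN})={f_lo + target:.3e}, "
                f"joint({_T_MAX})={f_hi + target:.3e}, target={target:.3e}"
            )
        ti = float(norm.isf(p[i]))  # independence start
        converged = False
        for _ in range(40):
            f = joint(ti)
            if f > 0.0:
                lo_b = ti
            else:
                hi_b = ti
            if abs(f) < 1e-11:
                converged = True
                break
            lov = t[: i + 1].copy()
            lov[i] = ti
            deriv = -norm.pdf(ti) * _conditional_rect(Ri, lov, i)
            step = f / deriv if deriv < -1e-300 else None
            nxt = ti - step if step is not None else None
            if nxt is None or not (lo_b < nxt < hi_b):
                nxt = 0.5 * (lo_b + hi_b)
            if abs(nxt - ti) < 1e-12:
                ti = nxt
                converged = True
                break
            ti = nxt
        if not converged:
            ti = brentq(joint, lo_b, hi_b, xtol=1e-10)
        t[i] = ti
    return t


@dataclass(frozen=True)
class TruncationProblem:
    """A solved multistage truncation problem.

    R is the correlation matrix among the m stage indices plus the aggregate
    genotype as the LAST variable; thresholds and proportions refer to the
    stages only.
    """

    R: np.ndarray
    thresholds: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        R = _validate_corr(self.R)
        t = np.asarray(self.thresholds, dtype=float)
        p = np.asarray(self.proportions, dtype=float)
        m = R.shape[0] - 1
        if t.shape != (m,) or p.shape != (m,):
            raise ValueError("thresholds/proportions must cover all stages (R includes H)")
        if np.any(p <= 0.0) or np.any(p > 1.0):
            raise ValueError("proportions must be in (0, 1]")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "proportions", p)

    @classmethod
    def solve(cls, R: np.ndarray, proportions: np.ndarray) -> "TruncationProblem":
        """Solve thresholds from proportions; R includes H as last variable."""
        R = _validate_corr(R)
        m = R.shape[0] - 1
        t = solve_thresholds(R[:m, :m], proportions)
        return cls(R, t, proportions)

    @property
    def n_stages(self) -> int:
        return self.R.shape[0] - 1

    @property
    def selected_fraction(self) -> float:
        return float(np.prod(self.proportions))


def selected_mean(problem: TruncationProblem, sigma_a: float) -> float:
    """E[H | I_k > t_k for all stages] · σ_a (kg).

    Tallis first moment: E[H|sel] = (1/α) Σ_k r_{H,k} φ(t_k) Φ_{m−1}(rect
    conditional on I_k = t_k), with α the joint selected fraction.
    """
    R, t = problem.R, problem.thresholds
    m = problem.n_stages
    alpha = problem.selected_fraction
    if alpha < 1e-12:
        raise ValueError("selection too extreme: joint selected fraction < 1e-12")
    r_h = R[m, :m]
    total = 0.0
    for k in range(m):
        if not np.isfinite(t[k]):
            continue  # unused stage (p=1) contributes nothing
        cond = _conditional_rect(R[:m, :m], t, k)
        total += r_h[k] * norm.pdf(t[k]) * cond
    return total / alpha * sigma_a


def univariate_intensity(p: float) -> float:
    """One-stage selection intensity i = φ(Φ⁻¹(1−p))/p; i(1) = 0."""
    if p <= 0.0 or p > 1.0:
        raise ValueError(f"proportion must be in (0, 1], got {p}")
    if p >= 1.0:
        return 0.0
    return float(norm.pdf(norm.isf(p)) / p)


def collapse_duplicate_stages(
    accuracies: np.ndarray, proportions: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Merge consecutive stages whose indices are perfectly correlated.

    For nested optimum indices corr(I_i, I_j) = acc_i/acc_j, so equal
    accuracies mean a duplicated index; truncating the same variable twice
    equals one truncation at the joint proportion.  Avoids the singular
    correlation matrices that plague multistage integration.
    """
    acc = list(np.asarray(accuracies, dtype=float))
    p = list(np.asarray(proportions, dtype=float))
    i = 1
    while i < len(acc):
        if abs(acc[i] - acc[i - 1]) <= tol * max(acc[i], 1e-12):
            p[i - 1] *= p[i]
            del acc[i], p[i]
        else:
            i += 1
    return np.array(acc), np.array(p)
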