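"""Self-contained test inputs: the default program configuration and random
small index problems with a known optimum accuracy.

Everything here is generated in memory with explicit seeds — no data files,
no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .index_engine import IndexMatrices, Trait
from .program import ProgramConfig, load_program, save_program

__all__ = [
    "RandomIndexProblem",
    "default_program",
    "random_index_problem",
    "nested_accuracy_problem",
    "two_stage_problem_with_accuracies",
]


def default_program() -> ProgramConfig:
    """The reference cooperative dairy program (all defaults; the budget is
    reconstructed from the cost parameters rather than stored)."""
    return ProgramConfig()


@dataclass(frozen=True)
class RandomIndexProblem:
    """A random positive-definite index problem with its known optimum.

    ``known_osi_accuracy`` is fixed at generation by rescaling G so that
    sqrt(G'P⁻¹G)/σ_a hits a drawn target — reproducible from (seed,
    n_sources) alone.
    """

    n_sources: int
    seed: int
    matrices: IndexMatrices
    trait: Trait
    known_osi_accuracy: float


def random_index_problem(
    n_sources: int,
    seed: int,
    trait: Trait | None = None,
    target_accuracy: float | None = None,
) -> RandomIndexProblem:
    """Generate P = A·Aᵀ + ridge (well-conditioned PD) and a G scaled to a
    known optimum-index accuracy in (0.2, 0.95)."""
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    rng = np.random.default_rng(seed)
    trait = trait or Trait(h2=0.25, sigma_p=700.0)
    va = trait.var_a
    A = rng.normal(size=(n_sources, n_sources + 2))
    P = (A @ A.T + 0.5 * np.eye(n_sources)) * va / (n_sources + 2)
    G = P @ rng.normal(size=n_sources)
    acc = math.sqrt(float(G @ np.linalg.solve(P, G))) / trait.sigma_a
    target = target_accuracy if target_accuracy is not None else rng.uniform(0.2, 0.95)
    G = G * (target / acc)
    m = IndexMatrices(P, G, tuple(f"src{i}" for i in range(n_sources)))
    return RandomIndexProblem(n_sources, seed, m, trait, float(target))


def two_stage_problem_with_accuracies(
    acc_stage1: float,
    acc_combined: float,
    seed: int = 0,
    trait: Trait | None = None,
) -> IndexMatrices:
    """A two-source nested index problem with prescribed stage accuracies.

    Source 1 alone yields an optimum-index accuracy of ``acc_stage1``; both
    sources together yield ``acc_combined``.  The correlation between the
    sources is drawn from the seed and the second source's covariance with
    the breeding value is solved accordingly, so different seeds give
    genuinely different problems with the same two accuracies.
    """
    if not (0.0 < acc_stage1 <= acc_combined <= 1.0):
        raise ValueError("need 0 < acc_stage1 <= acc_combined <= 1")
    rng = np.random.default_rng(seed)
    trait = trait or Trait(h2=0.25, sigma_p=700.0)
    va = trait.var_a
    rho = rng.uniform(-0.3, 0.3)
    a1 = acc_stage1
    # g'R⁻¹g = acc_combined² with g = (a1, c), R = [[1, ρ], [ρ, 1]]
    disc = (rho * a1) ** 2 - a1**2 + acc_combined**2 * (1.0 - rho**2)
    c = rho * a1 + math.sqrt(disc)
    P = va * np.array([[1.0, rho], [rho, 1.0]])
    G = va * np.array([a1, c])
    return IndexMatrices(P, G, ("stage1_source", "stage2_source"))


def nested_accuracy_problem(
    n_stages: int, seed: int, trait: Trait | None = None
) -> tuple[RandomIndexProblem, np.ndarray]:
    """A random problem together with the cumulative optimum accuracies of
    its nested source prefixes (one stage per added source block)."""
    trait = trait or Trait(h2=0.25, sigma_p=700.0)
    prob = random_index_problem(n_stages + 1, seed, trait)
    P, G = prob.matrices.P, prob.matrices.G
    cum = []
    for i in range(2, n_stages + 2):
        acc = math.sqrt(float(G[:i] @ np.linalg.solve(P[:i, :i], G[:i]))) / trait.sigma_a
        cum.append(min(acc, 1.0))
    return prob, np.array(cum)
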