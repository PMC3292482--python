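"""Selection-index construction for multistage breeding schemes.

An information source is any predictor available on a selection candidate —
its own genomic breeding value (GEBV), ancestors' estimated breeding values
(EBV), a mean of half-sib GEBVs, a progeny-test mean.  Each stage of a
selection path combines all sources available up to that stage into an
optimum selection index (OSI): the best linear predictor of the candidate's
true breeding value, with weights ``b = P^{-1} G`` where ``P`` is the
phenotypic covariance matrix of the sources and ``G`` their covariances with
the aggregate genotype.

All covariances are kept in trait units (kg² for the single milk trait);
standardisation happens only inside the truncation numerics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trait",
    "GenomicTest",
    "InfoSource",
    "IndexMatrices",
    "StageIndex",
    "NonPositiveDefiniteError",
    "gebv_source",
    "progeny_mean_source",
    "ancestor_ebv_source",
    "half_sib_gebv_mean_source",
    "cross_covariances",
    "assemble_matrices",
    "osi_stage_index",
    "stage_index_correlations",
]

#: relative eigenvalue tolerance below which P is rejected as singular
PD_RTOL = 1e-10

#: additive relationships between the relatives a source can target.
#: "hs" is the candidate's paternal half-sib group (unrelated to the dam side).
RELATIONSHIP = {
    ("self", "self"): 1.0,
    ("self", "sire"): 0.5,
    ("self", "dam"): 0.5,
    ("self", "mgs"): 0.25,
    ("self", "hs"): 0.25,
    ("sire", "sire"): 1.0,
    ("sire", "dam"): 0.0,
    ("sire", "mgs"): 0.0,
    ("sire", "hs"): 0.5,
    ("dam", "dam"): 1.0,
    ("dam", "mgs"): 0.5,
    ("dam", "hs"): 0.0,
    ("mgs", "mgs"): 1.0,
    ("mgs", "hs"): 0.0,
    ("hs", "hs"): 1.0,  # within-group relationships enter the group variance
}


def relationship(t1: str, t2: str) -> float:
    """Additive relationship between two source targets."""
    try:
        return RELATIONSHIP[(t1, t2)] if (t1, t2) in RELATIONSHIP else RELATIONSHIP[(t2, t1)]
    except KeyError:
        raise KeyError(f"unknown relationship pair ({t1!r}, {t2!r})") from None


class NonPositiveDefiniteError(ValueError):
    """Raised when a phenotypic covariance matrix is (numerically) singular."""


@dataclass(frozen=True)
class Trait:
    """A single quantitative trait in the breeding goal.

    Parameters
    ----------
    h2 : narrow-sense heritability, in (0, 1].
    sigma_p : phenotypic standard deviation (kg).
    econ_weight : economic weight of the trait in the aggregate genotype
        (scalar 1 for a single-trait goal).
    """

    h2: float
    sigma_p: float
    econ_weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")
        if self.sigma_p <= 0.0:
            raise ValueError(f"sigma_p must be positive, got {self.sigma_p}")
        if not math.isfinite(self.econ_weight):
            raise ValueError("econ_weight must be finite")

    @property
    def sigma_a(self) -> float:
        """Additive-genetic standard deviation (kg)."""
        return math.sqrt(self.h2) * self.sigma_p

    @property
    def var_a(self) -> float:
        return self.h2 * self.sigma_p**2


@dataclass(frozen=True)
class GenomicTest:
    """A genotyping product: GEBV accuracy and its per-individual cost (€)."""

    r_gebv: float
    cost_per_individual: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_gebv <= 1.0):
            raise ValueError(f"r_gebv must be in [0, 1], got {self.r_gebv}")
        if self.cost_per_individual < 0.0:
            raise ValueError("cost_per_individual must be >= 0")


@dataclass(frozen=True)
class InfoSource:
    """One information source on a selection candidate.

    ``variance`` and ``cov_with_tbv`` are in kg².  ``target`` names the
    relative whose breeding value the source measures and ``loading`` is the
    regression of the source on that relative's true breeding value (so
    ``cov_with_tbv = loading * a(target, self) * sigma_a²``); together they
    determine cross-covariances between sources under independent errors.
    """

    label: str
    variance: float
    cov_with_tbv: float
    target: str = "self"
    loading: float = 0.0
    origin_path: str = "none"

    def __post_init__(self) -> None:
        if self.variance <= 0.0:
            raise ValueError(f"source {self.label!r}: variance must be positive")

    def standalone_accuracy(self, trait: Trait) -> float:
        """Correlation of an index on this source alone with the candidate TBV."""
        return self.cov_with_tbv / (math.sqrt(self.variance) * trait.sigma_a)

    def check(self, trait: Trait) -> None:
        if self.cov_with_tbv**2 > self.variance * trait.var_a * (1 + 1e-12):
            raise ValueError(
                f"source {self.label!r} implies accuracy > 1 "
                f"(cov² {self.cov_with_tbv**2:.4g} > var·σ_a² "
                f"{self.variance * trait.var_a:.4g})"
            )


@dataclass(frozen=True)
class IndexMatrices:
    """Covariance algebra for the sources available up to a stage.

    P : phenotypic covariance matrix among sources (kg²), symmetric PD.
    G : covariances of sources with the aggregate genotype, already weighted
        by the economic weight (kg²).
    """

    P: np.ndarray
    G: np.ndarray
    source_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        G = np.asarray(self.G, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("P must be square")
        if G.shape != (P.shape[0],):
            raise ValueError("G must be a vector of length dim(P)")
        if not np.allclose(P, P.T, atol=1e-8 * (1 + np.abs(P).max())):
            raise ValueError("P must be symmetric")
        eig = np.linalg.eigvalsh(P)
        if eig[0] <= PD_RTOL * max(eig[-1], 1.0):
            raise NonPositiveDefiniteError(
                f"P is not positive definite: smallest eigenvalue {eig[0]:.3e} "
                f"(largest {eig[-1]:.3e})"
            )
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "G", G)

    @property
    def dim(self) -> int:
        return self.P.shape[0]

    def prefix(self, n: int) -> "IndexMatrices":
        """Matrices restricted to the first ``n`` sources (nested stage sets)."""
        return IndexMatrices(self.P[:n, :n], self.G[:n], self.source_labels[:n])


@dataclass(frozen=True)
class StageIndex:
    """An optimum selection index at one stage.

    b is the weight vector over the stage's sources; variance = b'Pb (kg²);
    cov_H = b'G (kg²); accuracy = cov_H / (sd(index)·σ_a).
    """

    b: np.ndarray
    variance: float
    cov_H: float
    accuracy: float
    stage_id: str

    def __post_init__(self) -> None:
        if self.variance <= 0.0:
            raise ValueError("index variance must be positive")
        if not (-1e-9 <= self.accuracy <= 1.0 + 1e-9):
            raise ValueError(f"accuracy {self.accuracy} outside [0, 1]")


def gebv_source(test: GenomicTest, trait: Trait) -> InfoSource:
    """The candidate's own GEBV, modelled as a heritability-one trait.

    Convention: variance = covariance with TBV = (r·σ_a)², so the regression
    of TBV on GEBV has slope one and an index on this source alone has
    accuracy exactly ``r_gebv``.
    """
    if test.r_gebv <= 0.0:
        raise ValueError("r_gebv = 0: degenerate GEBV source")
    v = (test.r_gebv * trait.sigma_a) ** 2
    return InfoSource("gebv", v, v, target="self", loading=test.r_gebv**2)


def progeny_accuracy(n_daughters: int, trait: Trait) -> float:
    """Accuracy of a sire EBV from a mean of ``n`` half-sib daughters:
    sqrt(n / (n + k)), k = (4 − h²)/h²."""
    k = (4.0 - trait.h2) / trait.h2
    return math.sqrt(n_daughters / (n_daughters + k))


def progeny_mean_source(n_daughters: int, trait: Trait) -> InfoSource:
    """Progeny-test information: the candidate's daughter-mean, expressed as
    an EBV-like source with standalone accuracy sqrt(n/(n+k))."""
    if n_daughters < 1:
        raise ValueError("n_daughters must be >= 1")
    rho = progeny_accuracy(n_daughters, trait)
    v = (rho * trait.sigma_a) ** 2
    return InfoSource("progeny_mean", v, v, target="self", loading=rho**2)


def ancestor_ebv_source(
    ancestor_accuracy: float,
    relationship_: float,
    trait: Trait,
    label: str = "ancestor_ebv",
    target: str = "sire",
) -> InfoSource:
    """EBV of an ancestor with known accuracy; the candidate's standalone
    accuracy from this source is ``relationship · ancestor_accuracy``."""
    if not (0.0 < ancestor_accuracy <= 1.0):
        raise ValueError(f"ancestor_accuracy must be in (0, 1], got {ancestor_accuracy}")
    if not (0.0 < relationship_ <= 1.0):
        raise ValueError(f"relationship must be in (0, 1], got {relationship_}")
    lam = ancestor_accuracy**2
    var = lam * trait.var_a
    cov = lam * relationship_ * trait.var_a
    return InfoSource(label, var, cov, target=target, loading=lam)


def half_sib_gebv_mean_source(
    n_half_sibs: int, test: GenomicTest, trait: Trait
) -> InfoSource:
    """Mean GEBV of ``n`` paternal half sibs of the candidate.

    Var(x̄) = r²σ_a²·(1 + (n−1)·0.25·r²)/n; cov with the candidate TBV is
    0.25·r²σ_a² (half sibs are related to the candidate by 0.25).
    """
    if n_half_sibs < 1:
        raise ValueError("n_half_sibs must be >= 1")
    if test.r_gebv <= 0.0:
        raise ValueError("r_gebv = 0: degenerate half-sib GEBV source")
    r2 = test.r_gebv**2
    var = trait.var_a * r2 * (1.0 + (n_half_sibs - 1) * 0.25 * r2) / n_half_sibs
    cov = 0.25 * r2 * trait.var_a
    return InfoSource("half_sib_gebv_mean", var, cov, target="hs", loading=r2)


def cross_covariances(sources: list[InfoSource], trait: Trait) -> np.ndarray:
    """Covariance matrix among sources implied by their targets and loadings,
    assuming independent prediction errors:
    cov(x_i, x_j) = λ_i λ_j a(t_i, t_j) σ_a².  Diagonal = stated variances."""
    n = len(sources)
    P = np.empty((n, n))
    for i, si in enumerate(sources):
        P[i, i] = si.variance
        for j in range(i + 1, n):
            sj = sources[j]
            P[i, j] = P[j, i] = (
                si.loading * sj.loading * relationship(si.target, sj.target) * trait.var_a
            )
    return P


def assemble_matrices(
    sources: list[InfoSource],
    cross_covs: np.ndarray | None,
    trait: Trait,
) -> IndexMatrices:
    """Assemble P and G for a list of sources in stage order.

    ``cross_covs`` may be given explicitly (its diagonal must match the
    source variances) or left None to derive it from the sources' targets.
    """
    if not sources:
        raise ValueError("need at least one information source")
    for s in sources:
        s.check(trait)
    if cross_covs is None:
        P = cross_covariances(sources, trait)
    else:
        P = np.array(cross_covs, dtype=float)
        diag = np.array([s.variance for s in sources])
        if not np.allclose(np.diag(P), diag, rtol=1e-9):
            raise ValueError("cross_covs diagonal inconsistent with source variances")
    G = np.array([s.cov_with_tbv for s in sources]) * trait.econ_weight
    return IndexMatrices(P, G, tuple(s.label for s in sources))


def osi_stage_index(m: IndexMatrices, trait: Trait, stage_id: str = "PED") -> StageIndex:
    """Optimum selection index on all sources in ``m``: b = P⁻¹G.

    For the best linear predictor b'Pb = b'G, so the accuracy is
    sqrt(b'G)/σ_a.
    """
    b = np.linalg.solve(m.P, m.G)
    var = float(b @ m.G)  # = b'Pb for the optimum index
    if var <= 0.0:
        raise ValueError("index has non-positive variance (no information)")
    cov_h = var
    acc = math.sqrt(var) / trait.sigma_a
    return StageIndex(b=b, variance=var, cov_H=cov_h, accuracy=min(acc, 1.0), stage_id=stage_id)


def stage_index_correlations(
    indices: list[StageIndex], m: IndexMatrices, trait: Trait | None = None
) -> np.ndarray:
    """Correlation matrix among stage indices plus the aggregate genotype.

    Index weight vectors are over nested prefixes of the sources in ``m``;
    shorter vectors are zero-padded.  The aggregate genotype is the LAST row
    and column.  ``trait`` may be omitted if any index has accuracy > 0
    (σ_a is then recovered from cov_H and accuracy).
    """
    k = len(indices)
    if k == 0:
        raise ValueError("need at least one stage index")
    dim = m.dim
    B = np.zeros((dim, k))
    for j, idx in enumerate(indices):
        nb = len(idx.b)
        if nb > dim:
            raise ValueError("index dimension exceeds source set of m")
        B[:nb, j] = idx.b
    cov = B.T @ m.P @ B
    cov_h = B.T @ m.G
    if trait is not None:
        sigma_a = trait.sigma_a
    else:
        ref = max(indices, key=lambda i: i.accuracy)
        if ref.accuracy <= 0:
            raise ValueError("cannot infer sigma_a from zero-accuracy indices")
        sigma_a = ref.cov_H / (math.sqrt(ref.variance) * ref.accuracy)
    full = np.empty((k + 1, k + 1))
    full[:k, :k] = cov
    full[:k, k] = full[k, :k] = cov_h
    full[k, k] = sigma_a**2
    d = np.sqrt(np.diag(full))
    R = full / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R
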