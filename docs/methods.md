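# Methods

This note documents the model, the numerical choices and the assumptions
behind `breedopt`, in the order the computation flows: information sources
→ stage indices → truncation selection → gain and cost per scheme → grid
search.

## Information sources and the index engine

All covariances are kept in trait units (kg² for the milk trait, with
σ_a = √h²·σ_p = 350 kg under the defaults h² = 0.25, σ_p = 700 kg);
standardisation happens only inside the truncation numerics.  Every source
is characterised by a variance, a covariance with the candidate's true
breeding value, a *target* relative and a *loading* λ (the regression of
the source on the target's breeding value):

* **GEBV**: modelled as a trait with heritability one; variance =
  covariance = (r_GEBV·σ_a)², so an index on the GEBV alone has accuracy
  exactly r_GEBV and the regression of the breeding value on the GEBV has
  slope one.
* **Ancestor EBV** with accuracy ρ and additive relationship a: variance
  ρ²σ_a², covariance a·ρ²σ_a², standalone accuracy a·ρ.
* **Progeny mean** of n daughters: an EBV-like source with accuracy
  √(n/(n+k)), k = (4−h²)/h² (0.932 for n = 99, h² = 0.25).
* **Paternal half-sib GEBV mean** of n half sibs: variance
  r²σ_a²(1+(n−1)·0.25·r²)/n, covariance 0.25·r²σ_a².

Cross-covariances between sources follow from an independent-errors
generative model, cov(xᵢ, xⱼ) = λᵢλⱼ a(tᵢ, tⱼ) σ_a², with a fixed
relationship table over {candidate, sire, dam, maternal grandsire,
paternal half-sib group}.  The covariance matrix P is rejected as singular
when its smallest eigenvalue falls below 10⁻¹⁰ times the largest —
collinear source sets fail loudly rather than silently.

**Pedigree model.** The default PED-stage source set is: dam EBV, sire
EBV, maternal-grandsire EBV, plus the half-sib GEBV mean (group size 25)
when the path's own plan genotypes its candidates.  This is a modelling
choice of this package — real programs differ in lactation counts and
half-sib structure — and every entry is driven by the configuration.  One
consequence: the package's PED accuracies (≈0.56–0.63 for males at
r_GEBV = 0.75) are higher than some published stage accuracies derived
from sparser pedigrees, so absolute gain levels should be compared across
configurations, not across publications.

**Ancestor regime.** Ancestors were themselves selected under the scheme,
so their EBV accuracy is taken as the index accuracy at the terminal stage
of the path they came from: a male candidate's sire is a bull sire (SS),
its dam a bull dam (DS), its maternal grandsire a cow sire (SD); a
heifer's sire/maternal grandsire are cow sires and her dam an unselected
cow known from one lactation (accuracy √h² = 0.5).  Terminal accuracies of
the ancestor generation are computed once per (path, terminal stage,
r_GEBV) from fixed progeny-test-era priors (sire/MGS 0.932, dam 0.5) — a
single pass up the pedigree.  Iterating this to a steady-state fixed point
would be possible but is deliberately not done; the single pass keeps the
search deterministic and cheap, and the induced error is second-order
(ancestor accuracies enter candidates' indices through relationship
factors ≤ 0.5).

## Truncation numerics

Rectangle probabilities P(Xᵢ > lᵢ ∀i) under N(0, R) use the Genz
sequential-conditioning transform with tensor-product Gauss–Legendre
quadrature over the first m−1 transformed variables (the last integrates
in closed form): 96 nodes for m = 2, 64 for m = 3, 32 for m = 4, fewer
beyond.  Absolute accuracy is ~10⁻⁷ (m ≤ 2), ~10⁻⁶ (m = 3–4) — two to
three orders of magnitude below the 0.025 resolution of the proportion
grid — and, unlike randomised quasi-Monte-Carlo integrators, every call is
bit-reproducible, which the determinism contract of the sweep requires.
Variables are ordered most-constraining-last; infinite bounds are
marginalised out first.

Truncation points are solved sequentially: tᵢ is the root of
P(I₁>t₁,…,Iᵢ>tᵢ) = Π_{k≤i} p_k with earlier thresholds held fixed, by a
bracket-safeguarded Newton iteration (the derivative −φ(tᵢ)·Φ_{m−1}(·|Iᵢ=tᵢ)
falls out of the same conditioning machinery; Brent-style bisection is the
fallback), to a residual below 10⁻¹¹.  The expected aggregate genotype of
the jointly selected group uses the Tallis first-moment formula.  Stages
whose indices are perfectly correlated (equal accuracies, e.g. a stage
that adds no information) are merged into one stage at the product
proportion before integration — highly correlated successive indices are
exactly the regime where multistage integration is numerically fragile.

For nested optimum indices the correlation structure needs no covariance
algebra: cov(Iᵢ, Iⱼ) = cov(Iᵢ, H) for best linear predictors on nested
source sets, hence corr(Iᵢ, Iⱼ) = accᵢ/accⱼ and corr(Iᵢ, H) = accᵢ.  The
grid search exploits this: a path plan's gain is a function of its
cumulative stage accuracies and proportions only.

## Decorrelated indices

The zero-covariance construction is implemented as Gram–Schmidt in the
P inner product: the stage's optimum weight vector is projected against
the (P-orthonormal) previous stage vectors and the residual normalised to
unit variance.  This is algebraically identical to solving the constrained
system with Lagrange multipliers and numerically stabler.  A stage whose
residual variance falls below 10⁻¹⁰ adds no independent information and is
rejected.  For nested stage sets the stage accuracies obey the Pythagorean
identity Σ accᵢ² = acc²_combined, which the fast path inside the optimiser
uses directly (acc₁ = a₁, accᵢ = √(aᵢ²−aᵢ₋₁²)); the explicit projection is
kept as the reference construction and the two are tested against each
other.  σᵢ in the decorrelated gain formula is interpreted as the
covariance of the *standardised* stage index with the aggregate genotype
(the unit-variance constraint makes the literal index standard deviation
1, which cannot carry kg); this interpretation reproduces the exact
one-stage equivalence of the two methods.

## Costs, budget and the grid search

The default item→stage mapping: male genotyping and the 150 € keeper
compensation (paid only for genotyped-then-culled calves) at the GS stage;
calf purchase (4 000 €) and rearing to maturity (213.5 d × 5 €/d) for the
males surviving all juvenile stages; test keeping (1 403 d × 4.5 €/d) and
test-mating compensation (3 000 €) for males entering PPT; female
genotyping at the DS GS stage with no compensation.  The 213.5 d and
1 403 d keeping periods are taken as given constants of the configuration.
The budget (719 050 € under the defaults) is recomputed from the
configuration at start-up, so modified programs get consistent budgets.
The 20% test-bull insemination capacity is not enforced as a separate
constraint: under the default budget at most 50 bulls can be tested, well
below the ~100-bull capacity, so the budget binds first.

Path plans enumerate every non-empty ordered stage subset; all but the
last used stage take grid proportions (0.01 + 0.025k by default), the last
is the dependent value that makes the product equal s_j/n_j, accepted when
≤ 1 + 10⁻¹².  Bull sires are drawn from the cow-sire cohort either by
tightening the final proportion (same information) or through an extra PPT
stage on the selected cow sires (additional information); both variants
are enumerated.  Costs are computed for every cross-classified scheme,
gains only for schemes within budget; per-path gains are cached per (plan,
regime) so the cross-classification reduces to sums.  Ties are broken by
lower cost, then enumeration order; two runs with the same configuration
produce byte-identical CSVs.  The dam→dam path is unselected (zero gain)
but its generation interval — 30 months by assumption, absent from the
published parameter table — stays in the ΔG_a denominator.

## Problem sizes used in the tests

The test suite runs the optimiser at proportion-grid steps 0.05–0.2 and a
reduced (r, C) plane (r ∈ {0.45, 0.6, 0.75, 0.9}, C ∈ {50, 150} €); one
full-resolution point (step 0.025) takes a few seconds, the complete
975-point published plane is reachable with `breedopt sweep` in roughly an
hour on one core but is not exercised in the suite.  Monte-Carlo oracles
for the truncated moments use 10⁶ draws at fixed seeds.

## What the fixtures do and do not emulate

Random index problems draw well-conditioned P = AAᵀ + ridge matrices with
a known optimum accuracy planted by rescaling G; they exercise the index
algebra, not biology.  The program configuration emulates the reference
cooperative program's published parameters exactly, but the pedigree
behind the PED stage is the package's own model (above).  Passing tests
therefore demonstrate the correctness of the index algebra, truncation
numerics, cost accounting and search — and the *qualitative* published
findings (genomic selection displaces progeny testing at r ≥ 0.45;
optimum indices dominate decorrelated ones; decorrelated optimisation
drifts to one-stage male selection; gain rises with r and is nearly flat
in C) — not the exact published gain figures, which depend on the
unrecoverable pedigree details and the dam→dam generation interval.

## Known limitations

One-generation responses only: selection-induced variance reduction (the
Bulmer effect) is not modelled, so multi-generation responses are
overstated; scheme rankings are much less affected than levels.
Inbreeding, discounted economics and opportunity costs of capital,
multi-trait goals, and stochastic (individual-based) simulation are out of
scope.  The ancestor regime is a single upward pass, not a steady-state
fixed point.  Proportions live on a discrete grid; the optimum is the best
grid point, not a continuous optimum.
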