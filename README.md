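# breedopt

Deterministic optimisation of multistage, multipath dairy-cattle breeding
schemes that include genomic selection.

Breeding organisations introducing genomic selection face a structural
question: in which selection paths, at which stages, and for which fraction
of the candidates should genotyping replace or complement pedigree
preselection and progeny testing — given that the genotyping budget is
capped and the accuracy (r_GEBV) and price (C_GEBV) of a genomic test keep
changing?  `breedopt` answers this for a four-pathway (Rendel–Robertson)
dairy program by exhaustive, fully deterministic grid search, for
quantitative geneticists and breeding-program designers who want predicted
one-generation responses rather than stochastic simulation.

## Model

Each path *j* (sire→sire, sire→dam, dam→sire, dam→dam) selects its parents
in up to three stages — pedigree information (PED), the candidate's own
GEBV (GS), progeny test (PPT).  At stage *i* all information sources
available so far are combined into an optimum selection index (OSI) with
weights **b**ᵢ = **P**ᵢ⁻¹**G**ᵢ, where **P** is the phenotypic covariance
matrix of the sources and **G** their covariances with the aggregate
genotype; the GEBV enters as a trait with heritability one whose
correlation with the breeding value is r_GEBV.  Successive stage indices
are correlated, so the gain of a path,

ΔG_j = z_j σ_a,

takes z_j as the expected aggregate genotype of the individuals jointly
surviving all truncation points — the first moment of a truncated
multivariate normal (Tallis), with rectangle probabilities computed by a
deterministic Genz-type sequential-conditioning quadrature and thresholds
solved so that P(I₁>t₁, …, Iᵢ>tᵢ) = Π p_k.

Alternatively the stage indices can be *decorrelated* (DSI, Xu–Muir): each
stage's index is constrained to zero covariance with all earlier stages
(unit variance, maximal covariance with the breeding value), so stages
become independent and ΔG_j = Σᵢ i(pᵢ) σᵢ with univariate intensities —
at the price of lower late-stage accuracies.  Annual gain is

ΔG_a = Σ_j ΔG_j / Σ_j L_j,

with path generation intervals L_j set by each path's terminal stage.
Costs follow a stage-dependent (NamKoong) model — every expense is paid by
the fraction of the cohort surviving to the stage where it is incurred —
and a scheme is admissible only if its total cost stays within the annual
budget (719 050 €, the cost of progeny testing 50 young bulls, recomputed
from the configuration).  The optimiser enumerates every valid
stage/proportion combination per path (the proportions of a path must
multiply to its fixed selected fraction s_j/n_j), cross-classifies the
paths, couples them through the ancestor-regime model (ancestors' EBV
accuracies depend on how their own path selects), and returns the feasible
scheme with maximal ΔG_a.

## Worked example

`python examples/03_decorrelated_indices.py` reconstructs the two-stage
decorrelation worked example:

```
optimum index accuracy, stage 1 (PED):      0.441
optimum index accuracy, stages 1+2 (GS):    0.754
decorrelated stage-2 accuracy:              0.612
covariance between the two stage indices:   -2.28e-17
Pythagorean check: 0.441² + 0.612² = 0.5685 = 0.754²
```

The decorrelated second stage exploits only the variance orthogonal to
stage 1, so its accuracy falls from 0.754 to √(0.754² − 0.441²) = 0.612
while the stage indices become exactly uncorrelated.

`python examples/05_optimize_scheme.py` runs the full grid search at
r_GEBV = 0.75 and C_GEBV = 150 € (proportion grid step 0.05):

```
OSI: best scheme at r_GEBV=0.75, C_GEBV=150 EUR
   SD: stages PED+GS     proportions 0.96/0.0208
   SS: stages PED+GS     proportions 0.96/0.0104
   DS: stages PED+GS     proportions 0.06/0.333
   dG_a = 241.8 kg/yr (0.69 genetic SD), cost 643,175 EUR (180/8988 schemes within budget)
```

Progeny testing disappears from the optimum: males are preselected on
pedigree, almost all of them genotyped, and 3 000 heifers are genotyped as
bull-dam candidates; the budget is dominated by female genotyping.  The
decorrelated method at the same point predicts 240.1 kg/yr and collapses
male selection to a single genomic stage — the characteristic distortion
that motivates using exact optimum indices.

The other examples cover stage-index accuracies (`01`), truncation
thresholds and intensities (`02`) and the cost ledger (`04`).  A thin CLI
exposes the same operations (`breedopt fixtures|evaluate|optimize|sweep`).

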