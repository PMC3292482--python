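"""Breeding-program description and regime-dependent index accuracies.

:class:`ProgramConfig` holds every biological, technical and economic
parameter of the cooperative dairy program: a 100 000-cow population, four
Rendel–Robertson pathways (sire→sire SS, sire→dam SD, dam→sire DS,
dam→dam DD), up to three selection stages per path (pedigree PED, genomic
GS, progeny test PPT), the cost rates, and the annual budget.

The pedigree model behind the PED stage
---------------------------------------
The information available on a candidate before its own genotyping is the
dam's EBV, the sire's EBV, the maternal-grandsire's EBV and — when the
path's plan genotypes its candidates — the mean GEBV of a paternal half-sib
group.  Ancestors were themselves selected under the scheme, so their EBV
accuracy equals the index accuracy at the terminal stage of the path they
came from (the *ancestor regime*): the sire of a male candidate is a bull
sire (SS path), its dam a bull dam (DS path), its maternal grandsire a cow
sire (SD path); a heifer's sire and maternal grandsire are cow sires and
her dam an unselected cow known only from her own lactation.  Terminal
accuracies of the ancestor generation are computed once per (path,
terminal stage, GEBV accuracy) from fixed progeny-test-era priors — a
single pass up the pedigree, no fixed-point iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .gain import PathSpec
from .index_engine import (
    GenomicTest,
    InfoSource,
    Trait,
    ancestor_ebv_source,
    assemble_matrices,
    gebv_source,
    half_sib_gebv_mean_source,
    osi_stage_index,
    progeny_accuracy,
    progeny_mean_source,
)

__all__ = ["ProgramConfig", "AccuracyModel", "load_program", "save_program"]

STAGE_ORDER = ("PED", "GS", "PPT")

#: which path each ancestor of a candidate was selected in; "COW" marks an
#: unselected dam known only from her own performance.
ANCESTOR_PATHS = {
    "SS": {"sire": "SS", "dam": "DS", "mgs": "SD"},
    "SD": {"sire": "SS", "dam": "DS", "mgs": "SD"},
    "DS": {"sire": "SD", "dam": "COW", "mgs": "SD"},
}


@dataclass
class ProgramConfig:
    """All parameters of the breeding program (defaults: the reference
    cooperative Holstein program for a single milk trait)."""

    # trait
    h2: float = 0.25
    sigma_p: float = 700.0  # kg
    # genomic test parameter ranges swept during optimisation
    r_gebv_min: float = 0.3
    r_gebv_max: float = 0.9
    r_gebv_step: float = 0.025
    c_gebv_min: float = 20.0  # €
    c_gebv_max: float = 400.0
    c_gebv_step: float = 10.0
    # population structure (head, per year where applicable)
    cows: int = 100_000
    cow_sire_demand: int = 10
    bull_sire_demand: int = 5
    male_candidates: int = 500
    bull_dam_demand: int = 1000  # contract matings
    daughters_per_sire: int = 99
    test_bull_insemination_share: float = 0.20
    # timing (months)
    age_first_calving: float = 26.0
    calving_interval: float = 12.0
    lactation_length: float = 10.0
    test_bull_maturity: float = 14.0
    bull_calf_purchase_age: float = 6.0
    # economics (€)
    calf_price: float = 4000.0
    keep_young_days: float = 213.5
    keep_young_cost_per_day: float = 5.0
    keep_test_days: float = 1403.0
    keep_test_cost_per_day: float = 4.5
    test_mating_compensation: float = 3000.0
    keeper_compensation: float = 150.0
    reference_test_bulls: int = 50
    budget: float | None = None  # € per year; None → recomputed from Eq-style reference
    # generation intervals per path and terminal stage (months)
    L_SS: dict = field(default_factory=lambda: {"PED": 23.0, "GS": 23.0, "PPT": 71.0})
    L_SD: dict = field(default_factory=lambda: {"PED": 23.0, "GS": 23.0, "PPT": 61.0})
    L_DS: dict = field(default_factory=lambda: {"PED": 26.0, "GS": 26.0})
    #: generation interval of the unselected dam→dam path; not part of the
    #: published parameter set — an explicit assumption of this package.
    l_dd: float = 30.0
    #: paternal half-sib group size whose mean GEBV enters the PED index
    #: when the path's plan genotypes its candidates
    n_half_sibs: int = 25

    def __post_init__(self) -> None:
        if self.budget is None:
            from .costs import reference_budget

            self.budget = reference_budget(self)

    # -- derived quantities -------------------------------------------------
    @property
    def trait(self) -> Trait:
        return Trait(h2=self.h2, sigma_p=self.sigma_p)

    @property
    def heifer_cohort(self) -> int:
        """Annual female calf crop: one calf per cow, equal sex ratio."""
        return self.cows // 2

    def path_specs(self) -> dict[str, PathSpec]:
        return {
            "SS": PathSpec("SS", self.male_candidates, self.bull_sire_demand,
                           ("PED", "GS", "PPT"), dict(self.L_SS)),
            "SD": PathSpec("SD", self.male_candidates, self.cow_sire_demand,
                           ("PED", "GS", "PPT"), dict(self.L_SD)),
            "DS": PathSpec("DS", self.heifer_cohort, self.bull_dam_demand,
                           ("PED", "GS"), dict(self.L_DS)),
            "DD": PathSpec("DD", self.heifer_cohort, self.heifer_cohort,
                           (), {}),
        }

    def L_months(self, path_id: str, terminal_stage: str | None) -> float:
        if path_id == "DD":
            return self.l_dd
        table = {"SS": self.L_SS, "SD": self.L_SD, "DS": self.L_DS}[path_id]
        if terminal_stage not in table:
            raise ValueError(f"no generation interval for {path_id} ending at {terminal_stage}")
        return float(table[terminal_stage])

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProgramConfig":
        return cls(**d)


def save_program(program: ProgramConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(program.to_dict(), fh, sort_keys=True)


def load_program(path) -> ProgramConfig:
    with open(path) as fh:
        return ProgramConfig.from_dict(yaml.safe_load(fh))


class AccuracyModel:
    """Cumulative optimum-index accuracies per path, stage set and regime.

    Instances cache by (path, used stages, ancestor accuracies); one model
    serves one (program, genomic test) pair.
    """

    def __init__(self, program: ProgramConfig, genomic: GenomicTest):
        self.program = program
        self.genomic = genomic
        self.trait = program.trait
        self._cum_cache: dict = {}
        self._term_cache: dict = {}

    # -- generation-0 priors ------------------------------------------------
    def _baseline_ancestors(self) -> dict[str, float]:
        """Progeny-test-era accuracies for the generation before the scheme:
        sires and maternal grandsires progeny tested, dams known from one
        lactation."""
        sire = progeny_accuracy(self.program.daughters_per_sire, self.trait)
        return {"sire": sire, "dam": math.sqrt(self.trait.h2), "mgs": sire}

    def terminal_accuracy(self, path_id: str, terminal_stage: str) -> float:
        """Index accuracy at a path's terminal stage for the ancestor
        generation (baseline priors one level further up)."""
        if path_id == "COW":
            return math.sqrt(self.trait.h2)  # own single lactation
        key = (path_id, terminal_stage)
        if key not in self._term_cache:
            used = {"PED": ("PED",), "GS": ("PED", "GS"), "PPT": ("PED", "PPT")}[terminal_stage]
            acc = self.cumulative(path_id, used, ancestors=self._baseline_ancestors())
            self._term_cache[key] = float(acc[-1])
        return self._term_cache[key]

    def ancestor_accuracies(self, path_id: str, regime: dict[str, str]) -> dict[str, float]:
        """EBV accuracies of a candidate's ancestors under a regime mapping
        each path to its terminal selection stage."""
        out = {}
        for role, apath in ANCESTOR_PATHS[path_id].items():
            if apath == "COW":
                out[role] = math.sqrt(self.trait.h2)
            else:
                out[role] = self.terminal_accuracy(apath, regime[apath])
        return out

    # -- source sets --------------------------------------------------------
    def _sources(self, used_stages: tuple[str, ...], upto: str,
                 ancestors: dict[str, float]) -> list[InfoSource]:
        trait, genomic = self.trait, self.genomic
        srcs = [
            ancestor_ebv_source(ancestors["dam"], 0.5, trait, "dam_ebv", "dam"),
            ancestor_ebv_source(ancestors["sire"], 0.5, trait, "sire_ebv", "sire"),
            ancestor_ebv_source(ancestors["mgs"], 0.25, trait, "mgs_ebv", "mgs"),
        ]
        genotyping = "GS" in used_stages and genomic.r_gebv > 0
        if genotyping:
            srcs.append(half_sib_gebv_mean_source(self.program.n_half_sibs, genomic, trait))
        pos = STAGE_ORDER.index(upto)
        if genotyping and pos >= STAGE_ORDER.index("GS"):
            srcs.append(gebv_source(genomic, trait))
        if upto == "PPT":
            srcs.append(progeny_mean_source(self.program.daughters_per_sire, trait))
        return srcs

    def cumulative(
        self,
        path_id: str,
        used_stages: tuple[str, ...],
        regime: dict[str, str] | None = None,
        ancestors: dict[str, float] | None = None,
    ) -> np.ndarray:
        """Cumulative optimum-index accuracies at each used stage.

        Information accumulates with age, not with selection: pedigree
        sources are available at every stage, the candidate's GEBV from the
        GS stage on (if the plan genotypes at all), the progeny mean only at
        PPT.
        """
        if ancestors is None:
            if regime is None:
                raise ValueError("either regime or explicit ancestor accuracies required")
            ancestors = self.ancestor_accuracies(path_id, regime)
        key = (path_id, tuple(used_stages),
               tuple(round(ancestors[r], 12) for r in ("sire", "dam", "mgs")))
        if key not in self._cum_cache:
            accs = []
            for stage in used_stages:
                m = assemble_matrices(self._sources(used_stages, stage, ancestors),
                                      None, self.trait)
                accs.append(osi_stage_index(m, self.trait, stage).accuracy)
            self._cum_cache[key] = np.array(accs)
        return self._cum_cache[key]
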