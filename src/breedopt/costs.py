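"""Stage-dependent breeding-cost model and the annual budget.

Every expense is tied to the selection stage at which it is incurred and
multiplied by the fraction of the initial cohort that survives to that
stage (the NamKoong cost function): an item of unit cost C applied at stage
i of a path with n_j initial candidates costs C·n_j·Π_{k<i} p_jk.
Compensation paid only for individuals *culled* at a genotyping stage
carries an extra factor (1 − p_ji).

Only costs that depend on the selection strategy are modelled; fixed
overheads (female performance recording, EBV computation, marketing, semen
processing) are outside the model.  The annual budget is reconstructed from
the program configuration as the cost of progeny testing a reference number
of young bulls (50 by default): purchase, rearing to maturity, keeping
through the test, and test-mating compensation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .index_engine import GenomicTest

if TYPE_CHECKING:  # pragma: no cover
    from .program import ProgramConfig
    from .scheme_search import SchemePlan

__all__ = [
    "CostItem",
    "CostLedger",
    "expense",
    "compensation_expense",
    "reference_budget",
    "default_cost_items",
    "scheme_cost",
]


@dataclass(frozen=True)
class CostItem:
    """One expense factor of one path.

    ``applies_at_stage`` is the 1-based position in the path's used-stage
    list at which the cost is incurred (individuals surviving the earlier
    stages pay it); position m+1 means "after the final stage", i.e. only
    the finally selected individuals pay.
    """

    label: str
    unit_cost: float
    applies_at_stage: int
    path_id: str
    mode: str = "standard"  # or "compensation"

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise ValueError("unit_cost must be >= 0")
        if self.applies_at_stage < 1:
            raise ValueError("applies_at_stage is 1-based")
        if self.mode not in ("standard", "compensation"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class CostLedger:
    """Per-(path, item) expenses, their total, and the budget verdict."""

    entries: dict[tuple[str, str], float]
    budget: float
    total: float = field(init=False)
    feasible: bool = field(init=False)

    def __post_init__(self) -> None:
        self.total = float(sum(self.entries.values()))
        self.feasible = self.total <= self.budget + 1e-6


def expense(item: CostItem, n_j: int, proportions) -> float:
    """C·n_j·Π_{k<i} p_jk — cost borne by individuals reaching stage i."""
    i = item.applies_at_stage
    surv = 1.0
    for k in range(min(i - 1, len(proportions))):
        surv *= proportions[k]
    return item.unit_cost * n_j * surv


def compensation_expense(item: CostItem, n_j: int, proportions) -> float:
    """C·n_j·Π_{k<i} p_jk·(1 − p_ji) — paid only for individuals culled at
    the genotyping stage i."""
    i = item.applies_at_stage
    if i > len(proportions):
        raise ValueError("compensation stage must be a used stage")
    return expense(item, n_j, proportions) * (1.0 - proportions[i - 1])


def reference_budget(program: "ProgramConfig") -> float:
    """Annual budget: progeny testing ``reference_test_bulls`` young bulls
    (purchase + rearing to maturity + test-period keeping + test-mating
    compensation per bull)."""
    per_bull = (
        program.calf_price
        + program.keep_young_days * program.keep_young_cost_per_day
        + program.keep_test_days * program.keep_test_cost_per_day
        + program.test_mating_compensation
    )
    return per_bull * program.reference_test_bulls


def default_cost_items(
    scheme: "SchemePlan", program: "ProgramConfig", genomic: GenomicTest
) -> list[CostItem]:
    """Concrete cost items for a scheme under the default item→stage mapping.

    Males (attributed to path SD; the SS selection reuses the same cohort):
    genotyping and culling compensation at the GS stage; calf purchase and
    rearing to maturity for the males surviving all juvenile stages (PED,
    GS); test-bull keeping and test-mating compensation for males entering
    PPT.  An extra PPT stage used only to pick bull sires from cow sires
    (path SS) adds the test costs for the cow sires entering it.  Females
    (path DS): genotyping at the GS stage, no compensation (bull dams are
    not purchased).  Path DD carries no strategy-dependent cost.
    """
    items: list[CostItem] = []
    sd, ss, ds = scheme.sd_plan, scheme.ss_plan, scheme.ds_plan
    m_sd = len(sd.used_stages)

    def pos(plan, stage):
        return plan.used_stages.index(stage) + 1

    if "GS" in sd.used_stages:
        items.append(CostItem("genotyping", genomic.cost_per_individual,
                              pos(sd, "GS"), "SD"))
        items.append(CostItem("keeper_compensation", program.keeper_compensation,
                              pos(sd, "GS"), "SD", mode="compensation"))
    rearing_stage = pos(sd, "PPT") if "PPT" in sd.used_stages else m_sd + 1
    young_keep = program.keep_young_days * program.keep_young_cost_per_day
    items.append(CostItem("calf_purchase", program.calf_price, rearing_stage, "SD"))
    items.append(CostItem("keeping_young", young_keep, rearing_stage, "SD"))
    test_keep = program.keep_test_days * program.keep_test_cost_per_day
    if "PPT" in sd.used_stages:
        items.append(CostItem("keeping_test", test_keep, pos(sd, "PPT"), "SD"))
        items.append(CostItem("test_matings", program.test_mating_compensation,
                              pos(sd, "PPT"), "SD"))
    if "PPT" in ss.used_stages and "PPT" not in sd.used_stages:
        items.append(CostItem("keeping_test", test_keep, pos(ss, "PPT"), "SS"))
        items.append(CostItem("test_matings", program.test_mating_compensation,
                              pos(ss, "PPT"), "SS"))
    if "GS" in ds.used_stages:
        items.append(CostItem("genotyping", genomic.cost_per_individual,
                              pos(ds, "GS"), "DS"))
    return items


def scheme_cost(
    scheme: "SchemePlan",
    program: "ProgramConfig",
    genomic: GenomicTest,
    items: list[CostItem] | None = None,
) -> CostLedger:
    """Evaluate all cost items of a scheme into a ledger against the budget."""
    if items is None:
        items = default_cost_items(scheme, program, genomic)
    n_by_path = {
        "SD": program.male_candidates,
        "SS": program.male_candidates,
        "DS": program.heifer_cohort,
        "DD": program.heifer_cohort,
    }
    plans = {"SD": scheme.sd_plan, "SS": scheme.ss_plan, "DS": scheme.ds_plan}
    entries: dict[tuple[str, str], float] = {}
    for item in items:
        plan = plans[item.path_id]
        fn = compensation_expense if item.mode == "compensation" else expense
        value = fn(item, n_by_path[item.path_id], plan.proportions)
        key = (item.path_id, item.label)
        entries[key] = entries.get(key, 0.0) + value
    return CostLedger(entries=entries, budget=program.budget)
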