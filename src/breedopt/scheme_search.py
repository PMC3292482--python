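"""Enumeration and budget-constrained grid search over breeding schemes.

A *path plan* fixes which stages a path uses and the proportion selected at
each; the product of the proportions must equal the path's overall selected
fraction s_j/n_j, which is enforced by computing the last used stage's
proportion as a dependent variable and keeping the plan only when it lands
in (0, 1].  Valid plans of the male path (SD), its bull-sire refinement
(SS) and the female path (DS) are completely cross-classified; costs are
computed for every scheme, genetic gain only for schemes within budget, and
the scheme with the highest annual gain wins (ties broken by lower cost,
then by enumeration order — runs are deterministic).

Bull sires are selected from the cow-sire cohort in one of two ways: by
tightening the final proportion of the SD plan (same information, higher
intensity) or by progeny testing the selected cow sires in an extra PPT
stage (additional information); both variants are enumerated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import costs as costs_mod
from .gain import GainResult, PathSpec, annual_gain, gain_dsi, gain_osi
from .index_engine import GenomicTest
from .program import AccuracyModel, ProgramConfig

__all__ = [
    "PathPlan",
    "SchemePlan",
    "SweepPoint",
    "proportion_grid",
    "enumerate_path_plans",
    "ss_variants",
    "apply_ancestor_regime",
    "evaluate_scheme",
    "optimize_point",
    "sweep",
    "sweep_points",
    "sweep_dataframe",
]

STAGE_ORDER = ("PED", "GS", "PPT")
_DEP_TOL = 1e-12


@dataclass(frozen=True)
class PathPlan:
    """Stage usage and selected proportions of one path.

    ``proportions`` aligns with ``used_stages``; a proportion of exactly 1
    marks a stage carried along but not selecting (treated as unused).
    """

    path_id: str
    used_stages: tuple[str, ...]
    proportions: tuple[float, ...]
    terminal_L: float  # months

    def __post_init__(self) -> None:
        if len(self.used_stages) != len(self.proportions):
            raise ValueError("one proportion per used stage required")
        if any(not (0.0 < p <= 1.0) for p in self.proportions):
            raise ValueError("proportions must be in (0, 1]")

    @property
    def selected_fraction(self) -> float:
        return float(np.prod(self.proportions))

    @property
    def terminal_stage(self) -> str | None:
        return self.used_stages[-1] if self.used_stages else None

    def sort_key(self) -> tuple:
        return (self.used_stages, self.proportions)


@dataclass(frozen=True)
class SchemePlan:
    """One breeding scheme: plans for SD, SS and DS (DD is unselected).

    The ancestor regime — the terminal stage of each path, which fixes the
    EBV accuracies of the next generation's ancestors — follows from the
    plans themselves.
    """

    sd_plan: PathPlan
    ss_plan: PathPlan
    ds_plan: PathPlan

    @property
    def ancestor_regime(self) -> dict[str, str]:
        return {
            "SS": self.ss_plan.terminal_stage,
            "SD": self.sd_plan.terminal_stage,
            "DS": self.ds_plan.terminal_stage,
        }


@dataclass(frozen=True)
class SweepPoint:
    """Optimisation result at one (r_GEBV, C_GEBV) grid point."""

    r_gebv: float
    c_gebv: float
    method: str
    best_plan: SchemePlan
    delta_g_a: float
    cost: float
    delta_g_by_path: dict[str, float]
    n_schemes: int
    n_feasible: int


def proportion_grid(step: float = 0.025, start: float = 0.01) -> np.ndarray:
    """Selected-proportion grid: start, start+step, … up to the largest
    value ≤ 1, plus 1.0 as the "stage unused" sentinel."""
    if not (0 < start <= 1) or step <= 0:
        raise ValueError("need 0 < start <= 1 and step > 0")
    k = int(np.floor((1.0 - start) / step + 1e-9))
    vals = np.round(start + step * np.arange(k + 1), 12)
    vals = vals[vals <= 1.0]
    if vals[-1] < 1.0:
        vals = np.append(vals, 1.0)
    return vals


def enumerate_path_plans(path: PathSpec, grid: np.ndarray) -> list[PathPlan]:
    """All valid stage combinations and grid assignments for one path.

    For every non-empty ordered subset of the available stages, all but the
    last used stage take free grid values (< 1); the last proportion is the
    dependent variable (s_j/n_j)/Π(free) and the plan is valid only when it
    lies in (0, 1].
    """
    ratio = path.selected_fraction
    if ratio > 1.0:
        raise ValueError("n_selected exceeds n_candidates")
    free_vals = [float(v) for v in grid if v < 1.0]
    plans: list[PathPlan] = []
    stages = path.available_stages
    for r in range(1, len(stages) + 1):
        for subset in itertools.combinations(stages, r):
            for free in itertools.product(free_vals, repeat=r - 1):
                prod = float(np.prod(free)) if free else 1.0
                dep = ratio / prod
                if dep <= 0.0 or dep > 1.0 + _DEP_TOL:
                    continue
                props = tuple(free) + (min(dep, 1.0),)
                plans.append(
                    PathPlan(path.path_id, subset, props,
                             path.L_by_terminal_stage[subset[-1]])
                )
    plans.sort(key=PathPlan.sort_key)
    return plans


def ss_variants(sd_plan: PathPlan, ss_spec: PathSpec, sd_spec: PathSpec) -> list[PathPlan]:
    """Bull-sire selection plans derived from a cow-sire plan.

    Variant "intensity": same stages, final proportion tightened by the
    ratio of the two paths' selected fractions.  Variant "extra PPT" (only
    when the cow-sire plan did not progeny test): the selected cow sires
    enter a progeny test and the bull sires are chosen on its outcome.
    """
    factor = ss_spec.selected_fraction / sd_spec.selected_fraction
    variants = []
    props = sd_plan.proportions[:-1] + (sd_plan.proportions[-1] * factor,)
    variants.append(
        PathPlan("SS", sd_plan.used_stages, props,
                 ss_spec.L_by_terminal_stage[sd_plan.used_stages[-1]])
    )
    if "PPT" not in sd_plan.used_stages and "PPT" in ss_spec.available_stages:
        variants.append(
            PathPlan("SS", sd_plan.used_stages + ("PPT",),
                     sd_plan.proportions + (factor,),
                     ss_spec.L_by_terminal_stage["PPT"])
        )
    return variants


def apply_ancestor_regime(
    regime: dict[str, str], program: ProgramConfig, genomic: GenomicTest
) -> dict[str, dict[str, float]]:
    """Ancestor EBV accuracies per path implied by a regime mapping each
    path to its terminal selection stage."""
    model = AccuracyModel(program, genomic)
    for pid, stage in regime.items():
        if pid not in ("SS", "SD", "DS"):
            raise KeyError(f"unknown regime path {pid!r}")
        if stage not in STAGE_ORDER:
            raise KeyError(f"unknown terminal stage {stage!r} for path {pid}")
    return {pid: model.ancestor_accuracies(pid, regime) for pid in ("SS", "SD", "DS")}


def _path_gains(
    scheme: SchemePlan,
    model: AccuracyModel,
    method: str,
) -> dict[str, float]:
    """ΔG_j per path for one scheme under OSI or DSI."""
    gain_fn = {"OSI": gain_osi, "DSI": gain_dsi}[method.upper()]
    regime = scheme.ancestor_regime
    trait = model.trait
    out = {"DD": 0.0}
    for pid, plan in (("SD", scheme.sd_plan), ("SS", scheme.ss_plan),
                      ("DS", scheme.ds_plan)):
        # SS selects from the same male cohort as SD: same information model
        acc = model.cumulative("SD" if pid == "SS" else pid, plan.used_stages, regime)
        out[pid] = gain_fn(np.array(plan.proportions), acc, trait)
    return out


def evaluate_scheme(
    scheme: SchemePlan,
    genomic: GenomicTest,
    program: ProgramConfig,
    method: str = "OSI",
    model: AccuracyModel | None = None,
) -> tuple[GainResult | None, costs_mod.CostLedger]:
    """Cost a scheme and, if it fits the budget, predict its genetic gain.

    Returns ``(None, ledger)`` for infeasible schemes — costs are always
    computed, gain only inside the budget.
    """
    ledger = costs_mod.scheme_cost(scheme, program, genomic)
    if not ledger.feasible:
        return None, ledger
    if model is None:
        model = AccuracyModel(program, genomic)
    gains = _path_gains(scheme, model, method)
    L = {
        "SD": scheme.sd_plan.terminal_L,
        "SS": scheme.ss_plan.terminal_L,
        "DS": scheme.ds_plan.terminal_L,
        "DD": program.l_dd,
    }
    return GainResult(delta_g_by_path=gains, L_by_path=L), ledger


def optimize_point(
    r_gebv: float,
    c_gebv: float,
    program: ProgramConfig,
    method: str = "OSI",
    grid_step: float = 0.025,
    grid_start: float = 0.01,
) -> SweepPoint:
    """Exhaustive grid search for the ΔG_a-maximal feasible scheme at one
    (r_GEBV, C_GEBV) point.

    Per-path gains and costs are cached per (plan, regime) and reused across
    the cross-classification, which then only sums path contributions.
    """
    genomic = GenomicTest(r_gebv, c_gebv)
    model = AccuracyModel(program, genomic)
    trait = program.trait
    gain_fn = {"OSI": gain_osi, "DSI": gain_dsi}[method.upper()]
    specs = program.path_specs()
    grid = proportion_grid(grid_step, grid_start)
    sd_plans = enumerate_path_plans(specs["SD"], grid)
    ds_plans = enumerate_path_plans(specs["DS"], grid)
    ds_terminals = sorted({p.terminal_stage for p in ds_plans})

    # female-path gains and costs, keyed by (plan index, male terminal stage)
    ds_gain: dict = {}
    ds_cost = []
    for k, dsp in enumerate(ds_plans):
        if "GS" in dsp.used_stages:
            gpos = dsp.used_stages.index("GS")
            n_genotyped = specs["DS"].n_candidates * float(np.prod(dsp.proportions[:gpos]))
        else:
            n_genotyped = 0.0
        ds_cost.append(n_genotyped * c_gebv)

    def ds_gain_at(k: int, t_sd: str) -> float:
        key = (k, t_sd)
        if key not in ds_gain:
            dsp = ds_plans[k]
            regime = {"SS": "PED", "SD": t_sd, "DS": dsp.terminal_stage}
            acc = model.cumulative("DS", dsp.used_stages, regime)
            ds_gain[key] = gain_fn(np.array(dsp.proportions), acc, trait)
        return ds_gain[key]

    male_gain: dict = {}

    def male_gain_at(plan: PathPlan, t_ss: str, t_sd: str, t_ds: str) -> float:
        key = (plan.used_stages, plan.proportions, t_ss, t_sd, t_ds)
        if key not in male_gain:
            regime = {"SS": t_ss, "SD": t_sd, "DS": t_ds}
            acc = model.cumulative("SD", plan.used_stages, regime)
            male_gain[key] = gain_fn(np.array(plan.proportions), acc, trait)
        return male_gain[key]

    best: tuple | None = None
    n_schemes = 0
    n_feasible = 0
    budget = program.budget
    l_dd = program.l_dd  # months, like the terminal_L values
    for sdp in sd_plans:
        for ssp in ss_variants(sdp, specs["SS"], specs["SD"]):
            scheme_proto = SchemePlan(sdp, ssp, ds_plans[0])
            male_items = [it for it in costs_mod.default_cost_items(
                scheme_proto, program, genomic) if it.path_id in ("SD", "SS")]
            plans_by_path = {"SD": sdp, "SS": ssp}
            male_cost = sum(
                (costs_mod.compensation_expense if it.mode == "compensation"
                 else costs_mod.expense)(
                    it, program.male_candidates, plans_by_path[it.path_id].proportions)
                for it in male_items
            )
            t_ss, t_sd = ssp.terminal_stage, sdp.terminal_stage
            for k, dsp in enumerate(ds_plans):
                n_schemes += 1
                total = male_cost + ds_cost[k]
                if total > budget + 1e-6:
                    continue
                n_feasible += 1
                t_ds = dsp.terminal_stage
                g_sd = male_gain_at(sdp, t_ss, t_sd, t_ds)
                g_ss = male_gain_at(ssp, t_ss, t_sd, t_ds)
                g_ds = ds_gain_at(k, t_sd)
                total_g = g_sd + g_ss + g_ds
                total_l = (sdp.terminal_L + ssp.terminal_L + dsp.terminal_L
                           + l_dd) / 12.0
                dga = total_g / total_l
                if (best is None or dga > best[0]
                        or (dga == best[0] and total < best[1])):
                    best = (dga, total, SchemePlan(sdp, ssp, dsp),
                            {"SD": g_sd, "SS": g_ss, "DS": g_ds, "DD": 0.0})
    if best is None:
        raise RuntimeError(
            f"no feasible scheme at r={r_gebv}, C={c_gebv} within budget {budget}"
        )
    dga, cost, plan, gains = best
    return SweepPoint(
        r_gebv=r_gebv, c_gebv=c_gebv, method=method.upper(), best_plan=plan,
        delta_g_a=dga, cost=cost, delta_g_by_path=gains,
        n_schemes=n_schemes, n_feasible=n_feasible,
    )


def sweep_points(
    r_range: tuple[float, float, float],
    c_range: tuple[float, float, float],
) -> list[tuple[float, float]]:
    """The (r_GEBV, C_GEBV) grid: inclusive ranges (min, max, step), sorted."""
    r_min, r_max, r_step = r_range
    c_min, c_max, c_step = c_range
    rs = np.round(np.arange(r_min, r_max + r_step / 2, r_step), 10)
    cs = np.round(np.arange(c_min, c_max + c_step / 2, c_step), 10)
    return [(float(r), float(c)) for r in rs for c in cs]


def sweep(
    r_range: tuple[float, float, float],
    c_range: tuple[float, float, float],
    program: ProgramConfig,
    method: str = "OSI",
    grid_step: float = 0.025,
    grid_start: float = 0.01,
    progress: bool = False,
) -> list[SweepPoint]:
    """Optimise every point of the (r_GEBV, C_GEBV) plane; output is sorted
    by (r, C) regardless of evaluation order."""
    points = []
    for r, c in sweep_points(r_range, c_range):
        points.append(optimize_point(r, c, program, method, grid_step, grid_start))
        if progress:  # pragma: no cover
            p = points[-1]
            print(f"r={r:.3f} C={c:.0f}: dGa={p.delta_g_a:.2f} kg/yr cost={p.cost:.0f}")
    return points


def _stages_str(plan: PathPlan) -> str:
    return "+".join(plan.used_stages)


def _props_str(plan: PathPlan) -> str:
    return "/".join(f"{p:.6g}" for p in plan.proportions)


def sweep_dataframe(points: list[SweepPoint]) -> pd.DataFrame:
    """Tabular sweep results (one row per grid point), ready for CSV."""
    rows = []
    for p in points:
        rows.append({
            "r_gebv": p.r_gebv,
            "c_gebv": p.c_gebv,
            "method": p.method,
            "delta_g_a": p.delta_g_a,
            "cost": p.cost,
            "feasible_schemes": p.n_feasible,
            "evaluated_schemes": p.n_schemes,
            "sd_stages": _stages_str(p.best_plan.sd_plan),
            "sd_props": _props_str(p.best_plan.sd_plan),
            "ss_stages": _stages_str(p.best_plan.ss_plan),
            "ss_props": _props_str(p.best_plan.ss_plan),
            "ds_stages": _stages_str(p.best_plan.ds_plan),
            "ds_props": _props_str(p.best_plan.ds_plan),
            "delta_g_sd": p.delta_g_by_path["SD"],
            "delta_g_ss": p.delta_g_by_path["SS"],
            "delta_g_ds": p.delta_g_by_path["DS"],
        })
    return pd.DataFrame(rows).sort_values(["r_gebv", "c_gebv"]).reset_index(drop=True)
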