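"""Plan enumeration, the overall-fraction constraint, scheme evaluation and
the grid-search optimiser."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breedopt import (
    GenomicTest,
    enumerate_path_plans,
    evaluate_scheme,
    optimize_point,
    proportion_grid,
    ss_variants,
    sweep,
    sweep_dataframe,
    sweep_points,
)
from breedopt.gain import PathSpec
from breedopt.scheme_search import PathPlan, SchemePlan


class TestProportionGrid:
    def test_default_grid_shape(self):
        g = proportion_grid()
        assert g[0] == pytest.approx(0.01)
        assert g[1] == pytest.approx(0.035)
        free = g[g < 1.0]
        assert len(free) == 40
        assert g[-1] == 1.0
        assert np.all(np.diff(g) > 0)
        assert np.all((g > 0) & (g <= 1))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.005, max_value=0.2),
        st.floats(min_value=0.01, max_value=0.3),
    )
    def test_grid_always_valid(self, start, step):
        g = proportion_grid(step, start)
        assert np.all((g > 0) & (g <= 1.0))
        assert np.all(np.diff(g) > 0)
        assert g[-1] == 1.0


class TestEnumeratePathPlans:
    def spec(self, n=500, s=10, stages=("PED", "GS", "PPT")):
        L = {"PED": 23.0, "GS": 23.0, "PPT": 61.0}
        return PathSpec("SD", n, s, stages, {k: L[k] for k in stages})

    def test_one_stage_plan_is_forced(self):
        plans = enumerate_path_plans(self.spec(stages=("PED",)),
                                     proportion_grid(0.1))
        assert len(plans) == 1
        assert plans[0].proportions == (0.02,)

    def test_dependent_proportion_above_one_rejected(self):
        # p1 = 0.01 forces p2 = 2 > 1: no such plan may appear
        plans = enumerate_path_plans(self.spec(), proportion_grid(0.025))
        for plan in plans:
            assert plan.selected_fraction == pytest.approx(0.02, abs=1e-9)
            assert all(0 < p <= 1 for p in plan.proportions)

    def test_count_matches_independent_enumeration(self):
        """Brute-force oracle: count all (subset, grid) combinations whose
        dependent last proportion lands in (0, 1]."""
        spec = self.spec(n=50_000, s=1000, stages=("PED", "GS"))
        grid = proportion_grid(0.05)
        free = [float(v) for v in grid if v < 1.0]
        ratio = 1000 / 50_000
        expected = 0
        for r in (1, 2):
            for subset in itertools.combinations(("PED", "GS"), r):
                for combo in itertools.product(free, repeat=r - 1):
                    dep = ratio / np.prod(combo) if combo else ratio
                    if 0 < dep <= 1.0 + 1e-12:
                        expected += 1
        plans = enumerate_path_plans(
            PathSpec("DS", 50_000, 1000, ("PED", "GS"),
                     {"PED": 26.0, "GS": 26.0}),
            grid,
        )
        assert len(plans) == expected

    def test_overselection_rejected(self):
        with pytest.raises(ValueError):
            PathSpec("SD", 10, 20, ("PED",), {"PED": 23.0})

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=400))
    def test_every_plan_satisfies_the_fraction_constraint(self, s):
        spec = self.spec(s=s)
        for plan in enumerate_path_plans(spec, proportion_grid(0.2)):
            assert plan.selected_fraction == pytest.approx(s / 500, rel=1e-9)


class TestSsVariants:
    def test_intensity_variant_tightens_last_stage(self, program):
        specs = program.path_specs()
        sd = PathPlan("SD", ("PED", "GS"), (0.5, 0.04), 23.0)
        va = ss_variants(sd, specs["SS"], specs["SD"])[0]
        assert va.used_stages == sd.used_stages
        assert va.proportions == (0.5, 0.02)
        assert va.selected_fraction == pytest.approx(0.01)

    def test_extra_ppt_variant_only_without_prior_test(self, program):
        specs = program.path_specs()
        sd_gs = PathPlan("SD", ("PED", "GS"), (0.5, 0.04), 23.0)
        sd_ppt = PathPlan("SD", ("PED", "PPT"), (0.1, 0.2), 61.0)
        assert len(ss_variants(sd_gs, specs["SS"], specs["SD"])) == 2
        assert len(ss_variants(sd_ppt, specs["SS"], specs["SD"])) == 1
        vb = ss_variants(sd_gs, specs["SS"], specs["SD"])[1]
        assert vb.used_stages[-1] == "PPT"
        assert vb.selected_fraction == pytest.approx(0.01)
        assert vb.terminal_L == 71.0


class TestEvaluateScheme:
    def test_reference_scheme_feasible_with_gain(self, program):
        specs = program.path_specs()
        sd = PathPlan("SD", ("PED", "PPT"), (0.1, 0.2), 61.0)
        ss = ss_variants(sd, specs["SS"], specs["SD"])[0]
        ds = PathPlan("DS", ("PED",), (0.02,), 26.0)
        gain, ledger = evaluate_scheme(SchemePlan(sd, ss, ds),
                                       GenomicTest(0.75, 150.0), program)
        assert ledger.total == pytest.approx(719_050.0)
        assert ledger.feasible
        assert gain is not None
        assert gain.delta_g_by_path["DD"] == 0.0
        assert gain.delta_g_a > 0

    def test_infeasible_scheme_reports_cost_but_no_gain(self, program):
        specs = program.path_specs()
        sd = PathPlan("SD", ("PED", "PPT"), (0.1, 0.2), 61.0)
        ss = ss_variants(sd, specs["SS"], specs["SD"])[0]
        ds = PathPlan("DS", ("PED", "GS"), (0.6, 1 / 30), 26.0)
        gain, ledger = evaluate_scheme(SchemePlan(sd, ss, ds),
                                       GenomicTest(0.75, 150.0), program)
        assert gain is None
        assert not ledger.feasible

    def test_one_stage_paths_make_methods_agree(self, program):
        specs = program.path_specs()
        sd = PathPlan("SD", ("PED",), (0.02,), 23.0)
        ss = ss_variants(sd, specs["SS"], specs["SD"])[0]
        ds = PathPlan("DS", ("PED",), (0.02,), 26.0)
        scheme = SchemePlan(sd, ss, ds)
        g_osi, _ = evaluate_scheme(scheme, GenomicTest(0.75, 150.0), program, "OSI")
        g_dsi, _ = evaluate_scheme(scheme, GenomicTest(0.75, 150.0), program, "DSI")
        assert g_dsi.delta_g_a == pytest.approx(g_osi.delta_g_a, abs=1e-9)


class TestOptimizePoint:
    def test_returns_feasible_maximum(self, program):
        pt = optimize_point(0.75, 150.0, program, "OSI", grid_step=0.2)
        assert pt.cost <= program.budget + 1e-6
        assert pt.delta_g_a > 0
        assert pt.n_feasible <= pt.n_schemes

    def test_deterministic_across_runs(self, program):
        a = optimize_point(0.6, 100.0, program, "OSI", grid_step=0.2)
        b = optimize_point(0.6, 100.0, program, "OSI", grid_step=0.2)
        assert a.delta_g_a == b.delta_g_a
        assert a.best_plan == b.best_plan


class TestSweep:
    def test_default_grid_cardinality(self):
        pts = sweep_points((0.3, 0.9, 0.025), (20.0, 400.0, 10.0))
        assert len(pts) == 975

    def test_single_point_range(self):
        assert sweep_points((0.75, 0.75, 0.025), (150.0, 150.0, 10.0)) == [(0.75, 150.0)]

    def test_sweep_rows_and_determinism(self, program, tmp_path):
        points = sweep((0.6, 0.75, 0.15), (150.0, 150.0, 10.0), program,
                       "OSI", grid_step=0.25)
        df = sweep_dataframe(points)
        assert len(df) == 2
        assert list(df["r_gebv"]) == [0.6, 0.75]
        # byte-identical CSVs across runs with the same configuration
        again = sweep_dataframe(
            sweep((0.6, 0.75, 0.15), (150.0, 150.0, 10.0), program, "OSI",
                  grid_step=0.25)
        )
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        df.to_csv(f1, index=False)
        again.to_csv(f2, index=False)
        assert f1.read_bytes() == f2.read_bytes()
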