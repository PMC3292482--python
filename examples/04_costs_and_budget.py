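"""The cost ledger of the reference progeny-testing scheme.

Fifty young bulls are purchased, reared and progeny tested each year; the
resulting cost defines the annual budget every optimised scheme must
respect.  A scheme that additionally genotypes 60% of the heifer cohort is
shown to break that budget.
"""

from breedopt import GenomicTest, default_program, reference_budget, scheme_cost
from breedopt.scheme_search import PathPlan, SchemePlan, ss_variants

program = default_program()
specs = program.path_specs()
genomic = GenomicTest(r_gebv=0.75, cost_per_individual=150.0)

print(f"annual budget (50 progeny-tested bulls): {reference_budget(program):,.0f} EUR")

sd = PathPlan("SD", ("PED", "PPT"), (0.1, 0.2), program.L_months("SD", "PPT"))
ss = ss_variants(sd, specs["SS"], specs["SD"])[0]
ds = PathPlan("DS", ("PED",), (0.02,), program.L_months("DS", "PED"))
ledger = scheme_cost(SchemePlan(sd, ss, ds), program, genomic)
print("\nreference scheme ledger:")
for (path, label), euro in sorted(ledger.entries.items()):
    print(f"  {path:>3} {label:<16} {euro:>10,.0f} EUR")
print(f"  total {ledger.total:,.0f} EUR -> feasible: {ledger.feasible}")

ds_gs = PathPlan("DS", ("PED", "GS"), (0.6, 1 / 30), program.L_months("DS", "GS"))
ledger2 = scheme_cost(SchemePlan(sd, ss, ds_gs), program, genomic)
print(f"\nadding genotyping of 30 000 heifers at 150 EUR: "
      f"total {ledger2.total:,.0f} EUR -> feasible: {ledger2.feasible}")
print("Genotyping large female cohorts dominates every other cost item.")
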