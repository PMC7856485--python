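"""Derive a median-based OAR constraint table from a historical cohort.

Generates a synthetic historical cohort (10 plans, 36 Gy / 20 fractions),
loads it into an in-memory registry, and derives the V5/V10/V20 constraint
table: each cell is the cohort median of that organ's VxGy, i.e. a planning
goal that half of past accepted plans met.
"""

from dvhregistry import Registry, derive_constraints
from dvhregistry.constraints import summarize_cohort_doses
from dvhregistry.synthgen import StudyConfig, generate_cohorts

pre, _ = generate_cohorts(StudyConfig(seed=20141201))
registry = Registry(":memory:")
registry.define_cohort("historical", [registry.insert_plan(p) for p in pre])

table = derive_constraints(registry, "historical")
print(f"Constraints from cohort 'historical' ({len(pre)} plans, "
      f"{table.rx_dose:g} Gy / {table.rx_fractions} fx)\n")
print(f"{'organ':14s}" + "".join(f"V{t:g}Gy".rjust(8) for t in table.thresholds))
for organ, cells in table.rows.items():
    print(f"{organ:14s}" + "".join(f"{cells[t]:8.0f}" for t in table.thresholds))

if table.saturated:
    print(f"\nadvisory: {', '.join(table.saturated)} are saturated (100/100) at "
          "the two lowest thresholds - their constraints carry no planning "
          "information there.")

print("\nCohort Dmean summaries (Gy):")
for s in summarize_cohort_doses(registry, "historical"):
    print(f"  {s.organ:14s} mean {s.mean:5.2f}  median {s.median:5.2f}  sd {s.sd:4.2f}")
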