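"""Phase II: cheapest staffing for one day of the packaged case study.

Loads the lightest day of the eight-day hospital census (21 patients,
98 care hours), builds the integer staffing instance with the default
parameters (15% absence buffer, one worker minimum per shift, balance
bound 1) and solves it exactly.
"""

from nursedim import (
    ModelParameters,
    Skill,
    build_instance,
    hsj_eight_days,
    phase1,
    solve,
)

case = hsj_eight_days()
census = case.censuses[3]  # Saturday 2016-09-10
profile = phase1(census)
print(f"{census.unit}, {census.date}: {profile.care_hours:.1f} care hours, "
      f"nurse ratio {profile.nurse_ratio_pct}%")

instance = build_instance(profile, ModelParameters())
solution = solve(instance)

print("           morning afternoon night1 night2")
for skill in Skill:
    m, a, n1, n2 = solution.vector(skill)
    print(f"{skill.value:>11} {m:7d} {a:9d} {n1:6d} {n2:6d}")
print(f"total staff {solution.total_staff}, "
      f"salary cost {solution.objective_cost:.1f} m.u.")

# Each worker is priced at shift length x hourly rate (nurse 1.0 m.u./h,
# technician 0.6, +37.5% at night); the solver returns the cheapest
# integer staffing that covers the demand and all workforce rules.
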