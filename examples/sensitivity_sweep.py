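"""What-if analysis: minimum cover and balance bound versus cost.

Re-solves one day's staffing over a 3x3 grid of the minimum staff per
shift (1..3) and the morning/afternoon balance bound (1..3), the sweep a
planner runs before fixing unit rules.
"""

from nursedim import hsj_eight_days, phase1, sweep

profile = phase1(hsj_eight_days().censuses[3])  # Saturday, 98 care hours
result = sweep(profile, min_staff_values=(1, 2, 3), alpha_values=(1, 2, 3))

cols = ["min_staff", "alpha", "nurse_total", "tech_total",
        "total_staff", "total_cost"]
print(result.table[cols].to_string(index=False))

# Raising the minimum cover forces extra workers into the expensive night
# shifts, so cost climbs with min_staff; relaxing the balance bound only
# redistributes workers between morning and afternoon, so at a fixed
# minimum cover the optimal cost is unchanged across alpha.
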