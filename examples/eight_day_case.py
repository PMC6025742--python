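"""The full eight-day case: model staffing versus the actual roster.

Runs Phase I + Phase II for every day of the packaged hospital census and
compares the required totals against the unit's constant real roster of
4 nurses and 22 technicians.
"""

from nursedim import compare_actual, hsj_eight_days, multiday

case = hsj_eight_days()
report = multiday(case.censuses)

cols = ["date", "care_hours", "nurse_ratio_pct",
        "nurse_total", "tech_total", "total_staff", "total_cost"]
print(report.table[cols].to_string(index=False))
print(f"model total staff across days: min {report.min_total_staff}, "
      f"max {report.max_total_staff}")

diff = compare_actual(report, case.actual_nurses, case.actual_technicians)
print(diff[["date", "model_total", "actual_total",
            "nurse_diff", "technician_diff", "total_diff"]]
      .to_string(index=False))

# Positive nurse_diff = the model needs more nurses than the roster holds:
# the ward runs short of nurses every day under the COFEN skill mix, while
# carrying more technicians than required.
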