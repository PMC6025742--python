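"""Phase I: from a patient census to care-hour demand and nurse ratio.

Builds one day's census of a general inpatient ward, applies the COFEN
care standard (3.8/5.6/9.4/17.9 h per patient by severity) and prints the
required daily care hours plus the minimum nurse percentage under both
ratio rules.
"""

from nursedim import CareStandard, PatientCensus, phase1

census = PatientCensus(minimal=21, intermediary=10, semi_intensive=3,
                       intensive=0, unclassified=0,
                       unit="example ward")
standard = CareStandard()

for rule in ("weighted", "dominant"):
    profile = phase1(census, standard, ratio_rule=rule)
    print(f"{rule:>8} rule: care hours = {profile.care_hours:.1f} h/day, "
          f"nurse ratio = {profile.nurse_ratio_pct}%")

# The care hours are what the whole staff must jointly deliver each day;
# the ratio is the minimum share of nurses (vs technicians) in the team.
# The weighted rule lets the three semi-intensive patients (42% category)
# pull the ratio above the 33% of the dominant minimal-care category.
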