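# nursedim

Multi-skill, multi-shift nurse staffing for hospital units: given a
severity-stratified patient census, determine the cheapest legal team of
nurses and nursing technicians per shift.

Hospital units must staff around the clock against guideline-mandated care
levels. In the Brazilian context, COFEN Resolution 293/2004 prescribes a
minimum number of daily nursing care hours per inpatient by illness
severity — 3.8 h (minimal), 5.6 h (intermediary), 9.4 h (semi-intensive),
17.9 h (intensive) — a minimum percentage of nurses (vs technicians) in the
workforce, and a 15% Technical Safety Index (TSI) buffering all absences.
`nursedim` is for planners dimensioning a unit's permanent pool at the
strategic level: it turns a census into demand (Phase I) and solves an
integer program assigning staff to shifts at minimum salary cost (Phase II).

## The model

**Phase I.** For a census with `N_c` patients in severity category `c`,
the required daily care hours are `H = Σ_c N_c · h_c` with `h_c` the
per-patient coefficients above (unclassified patients count as
intermediary). The minimum nurse fraction `prop` comes from the category
percentages (33/33/42/52%), either by the dominant-category rule or by the
default care-hour-weighted rule.

**Phase II.** Integer variables `x_{i,s}` count workers of skill
`i ∈ {nurse, technician}` on shift `s ∈ {morning, afternoon, night 1,
night 2}` (night cohorts alternate nights and must be equal). Continuous
auxiliary variables `y_{i,u}`, `u ∈ {morning, afternoon, night}`, carry the
pre-buffer staff levels. With shift lengths `L` (6/6/12 h by default),
TSI `p` and balance bounds `α_i`:

```
min  Σ_{i,s} x_{i,s} · L_{i,s} · rate_i · (1 + 0.375·[s is night])     (7)
s.t. Σ_i ( L_i,M y_i,M + L_i,A y_i,A + 2 L_i,N y_i,N ) ≥ H            (1)
     x_{i,M} ≥ (1+p) y_{i,M},  x_{i,A} ≥ (1+p) y_{i,A},
     x_{i,N1} + x_{i,N2} ≥ (1+p) · 2 y_{i,N}                          (2)
     Σ_s x_{nurse,s} ≥ prop · Σ_{i,s} x_{i,s}                         (3)
     |x_{i,M} − x_{i,A}| ≤ α_i                                        (4)
     x_{i,N1} = x_{i,N2}                                              (5)
     x_{i,s} ≥ min_staff_{i,s}                                        (6)
```

Salary rates default to 1 m.u./h for nurses, 0.6 for technicians, +37.5%
at night; both night cohorts are paid. The demand/TSI algebra admits a few
readings; `ModelVariant` makes the choice explicit (see
`docs/methods.md`). The solver is an exact, deterministic depth-first
branch-and-bound, verified against an exhaustive-enumeration oracle and an
independent MILP solver.

## Worked example

The package ships the eight-day census of a real inpatient unit
(`nursedim.hsj_eight_days()`). Staffing its lightest day:

```python
from nursedim import ModelParameters, build_instance, hsj_eight_days, phase1, solve

census = hsj_eight_days().censuses[3]          # Saturday: 13/7/1/0 patients
profile = phase1(census)                       # Phase I
solution = solve(build_instance(profile, ModelParameters()))
```

prints (via `python examples/single_day_staffing.py`):

```
In. U 4th floor PRT/CNV, 2016-09-10: 98.0 care hours, nurse ratio 34%
           morning afternoon night1 night2
      nurse       2         2      1      1
 technician       3         4      1      1
total staff 15, salary cost 102.0 m.u.
```

98.0 h is the COFEN demand of the 21-patient census; 34% is the weighted
nurse ratio; the staffing shown is the cheapest one covering the buffered
demand with all workforce rules, at 102.0 monetary units per day. The
other scripts in `examples/` demonstrate the sensitivity sweep over
minimum cover and balance parameters, the eight-day report, and the
comparison against the unit's actual roster of 4 nurses + 22 technicians
(which falls short of nurses every day, and short of two workers in total
on the busiest Wednesdays).

A CLI mirrors the library:

```sh
nursedim multiday --census src/nursedim/data/hsj_table2.csv \
         --actual-nurses 4 --actual-technicians 22
nursedim sweep --census src/nursedim/data/hsj_table2.csv --date 2016-09-10
nursedim validate --census src/nursedim/data/hsj_table2.csv \
         --date 2016-09-12 --nurses 2,3,1,1 --technicians 5,5,1,1
```

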