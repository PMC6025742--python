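# Methods

## Scope and decision level

`nursedim` dimensions the *permanent pool* of a single hospital unit — how
many nurses and nursing technicians to attach to each shift over a
long-term horizon — from a per-day patient census. It does not schedule
individuals (rostering), re-plan after disruptions, or dimension floating
pools shared across units; those are downstream decisions that take this
package's output as input. The demand is stated per day because the care
guidelines are.

## Phase I: demand

Care hours are a linear functional of the census,
`H = Σ_c N_c · h_c`, with COFEN 293/2004 coefficients
`h = (3.8, 5.6, 9.4, 17.9)` h/patient/day across the four severity
categories. Unclassified patients are folded into the intermediary
category before any computation.

Two nurse-ratio rules coexist:

* **dominant** — the percentage (33/33/42/52%) of the category with the
  most patients, ties resolved toward higher acuity. This is the rule as
  the guideline states it; for a ward dominated by minimal care it always
  returns 33%.
* **weighted** (default) — the care-hour-weighted mean of the category
  percentages, rounded to the nearest integer percent, half away from
  zero: `round(Σ_c N_c h_c π_c / Σ_c N_c h_c)`. On the packaged eight-day
  unit this reproduces every published per-day ratio (34–35%), which the
  dominant rule does not. The weighted rule is our reconstruction of how
  those figures arise; both rules are exposed and the discrepancy is
  deliberate surface, not hidden.

## Phase II: the staffing program

Variables, constraints and objective are given in the README. Points that
were genuinely open, and how this package resolves them:

* **Variant system.** The published description of the model leaves four
  algebraic details ambiguous. `ModelVariant` pins each one:
  * `tsi_scope` — where `x ≥ (1+p)·y` binds: per cell (default), pooled
    per skill, or pooled globally. Pooling only relaxes the link.
  * `aux_integrality` — auxiliary pre-buffer levels continuous (default)
    or integer.
  * `night_demand_hours` — whether both night cohorts' hours meet one
    day's demand (default) or only one cohort's. Each cohort works every
    other night, but the model prices both and is solved for a single
    day; under the single-cohort reading several published reference
    staffings would be demand-infeasible, under the default all are
    feasible. That feasibility is the criterion that fixed the default.
  * `prop_counting` — skill mix over all employees (default) or over the
    staff present on one day (one night cohort).
* **Skill mix** enters as the exact inequality
  `Σ x_nurse ≥ prop · Σ x`; `required_nurse_count` (the ceiling form)
  exists for reporting only.
* **Balance** applies to morning vs afternoon only; the night cohorts are
  tied by parity instead.
* **Variable bounds.** Search bounds are
  `ub = min_staff + ceil((1+p)·H / min shift length)` per cell: even the
  least productive cell alone could cover the whole buffered demand at
  that bound, so no optimum is excluded.

## Solver

An exact depth-first branch-and-bound written for this 6-variable lattice
(night parity is substituted out first, halving the night dimensionality):

* branch order: cells sorted by salary per optimistically delivered care
  hour, ascending, so cheap coverage is explored first;
* node bound: committed salary + minimum cover of unassigned cells +
  residual demand priced at the cheapest remaining rate; nodes are pruned
  only when strictly worse than the incumbent, so cost ties are fully
  explored;
* structural pruning: balance restricts branch ranges directly; a branch
  is cut when the remaining cells cannot reach the demand or the nurse
  fraction even at their bounds;
* tie-break: among equal-cost staffings the lexicographically smallest
  (total staff, nurse vector, technician vector) wins — repeated solves
  are bit-identical;
* infeasibility raises a typed error naming the constraint families that
  still bind at the most generous staffing the bounds allow.

Verification is dual-route: `solve_oracle` exhaustively enumerates the
bounded lattice (refusing instances beyond its cap — it exists to check
the solver, not to replace it), and the tests additionally cross-check
objectives against an off-the-shelf MILP solver on seeded random
instances. Under default rates the salary per delivered hour orders as
day technician (0.6) < night technician (0.825) < day nurse (1.0) <
night nurse (1.375), which is why optima lean on day technicians and
keep nights at the minimum unless the skill mix forces otherwise.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `hours_per_patient` | h/patient/day | 3.8/5.6/9.4/17.9 | COFEN care coefficients |
| `nurse_pct` | % | 33/33/42/52 | COFEN nurse share per category |
| `tsi` | fraction | 0.15 | absence buffer over pre-buffer levels |
| `prop` | fraction | from Phase I | minimum nurse share of the team |
| shift lengths | h | 6/6/12 | morning/afternoon/night, both skills |
| hourly rates | m.u./h | 1.0 / 0.6 | nurse / technician (confidential real wages abstracted) |
| `night_premium` | fraction | 0.375 | night wage uplift, both cohorts paid |
| `alpha` | workers | 1 | max morning−afternoon gap per skill |
| `min_staff` | workers | 1 | per skill and shift |

## Synthetic data

`random_census` draws per-category counts uniformly from ranges shaped
like the packaged unit (a general ward dominated by minimal care,
intensive care essentially absent: minimal 10–25, intermediary 5–12,
semi-intensive 0–4, intensive 0–1, unclassified 0–3). It emulates
day-to-day census variability only — counts are independent across days
and categories, with no admission/discharge dynamics, weekday effects or
occupancy ceilings — so tests passing on it show correctness of the
computations, not forecast quality on real wards. The solver's property
tests use a separate seeded instance generator (default seed 20160907)
drawing demand 0–60 h, TSI in {0, 0.15, 0.3}, nurse share 0–0.6, balance
0–3 and minimum cover 0–1, with per-cell bounds capped at 3 so the
enumeration oracle stays cheap; monotonicity grids reuse it with cap 6.
These sizes keep the full suite under half a minute while covering the
lattice densely.

## Numerical choices

* Care hours and money are floats; constraint tolerance 1e-6, cost-tie
  tolerance 1e-9, care-hour equality asserted at 1e-9.
* The weighted ratio rounds half away from zero; `required_nurse_count`
  uses `ceil(prop·total − 1e-9)` so exact products do not round up.
* Degenerate inputs: zero demand with zero minima yields the empty
  staffing at cost 0; an all-zero census has defined care hours (0) but
  no defined nurse ratio (error).

## Known limitations

* The published per-day *optimal* staffings of the case study are not
  reproduced as optima: no examined variant makes all of them optimal
  (several published configurations staff two nurses per night cohort
  where a cheaper feasible staffing exists), and the exact per-run
  parameters are not recoverable. They ship as feasibility references,
  clearly separated from model optima, and the solver is validated by
  property instead.
* One unit, one day at a time; no stochastic demand, no per-shift demand
  split beyond minimum cover, no individual scheduling.
* Monetary unit is abstract; real wage structures (seniority, overtime)
  are out of scope.
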