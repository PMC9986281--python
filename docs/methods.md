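# Methods

## Injury-deterioration model

Casualties occupy three states: minor (G), severe (R), dead (D). Without
treatment the state evolves once per time unit as a Markov chain — G→R with
probability `p_gr`, R→D with probability `p_rd`, D absorbing. Defaults are
`p_rd = 0.1` and `p_gr = 0.05` per unit, following the standard
injury-transition literature for mass-casualty triage.

The scheduling objective does not use the exact chain but a **linear
accumulation rule**: a severe casualty waiting `t` units dies with
probability `min(1, p_rd·t)`; a minor casualty accumulates nothing until the
**evolution threshold** `T = 1/p_gr` (20 units at defaults, the time at
which the accumulated G→R probability reaches 1) and `min(1, p_rd·(t−T))`
beyond it. A wait exactly equal to the threshold still yields 0 (the zero
branch is closed on the right), and an infinite/big-M wait maps to exactly 1
before any arithmetic. The exact chain gives the geometric law
`1 − (1−p_rd)^t`, which the linear rule overstates by under 11% relative for
`p_rd·t ≤ 0.3`; the simulator (`injury.simulate_trajectory`) exists so users
can quantify that gap themselves, and the test suite pins it at ≤ 15%
relative in that regime. Both views are exposed; the linear rule is the
objective's default because it is the standard choice in this model class
and keeps the objective piecewise-linear in waiting time.

**Time unit.** Deterioration probabilities are quoted per evolution period
while distances and speeds are km and km/h; the package fixes one evolution
period = one hour by default (`TransitionParams.time_unit` is a label, all
waits are expressed in it). With per-minute periods and 30 h horizons every
multi-hour wait would saturate at probability 1 and the objective would
degenerate to a step function; per-hour periods keep waits of a few hours in
the informative range of the piecewise law.

## Network and failures

The network is bipartite — affected points × medical points — with no
intermediate road nodes. Each route has distance `d` (km) and damage degree
`ε ∈ [0,1]`:

* `ε ≤ 0.5`: passable; ambulances drive the generalized distance `d(1+ε)`
  at `v_h` (40 km/h default). The boundary is inclusive.
* `ε > 0.5`: disrupted; helicopters fly the raw distance at `v_n`
  (120 km/h), unaffected by road damage.

Big-M (default 10⁶, validated to exceed every finite travel time by ≥ 10³)
stands for "unreachable". Facility failures are discrete scenarios (`β = 0`
failed); a group assigned to a failed facility is redirected to the open
facility with minimum one-way travel time, ties to the lowest id for
reproducibility. The redirected trip is priced at the backup leg only by
default; `reassignment_time="additive"` also charges the original leg,
for the reading in which the failure is discovered en route. Neither
behavior is asserted as uniquely correct — the additive reading
double-counts when failures are known before departure, which modern
remote sensing makes the typical case.

## Schedule evaluation

Casualty groups are one per (affected point, live state) by default; finer
groupings can be passed explicitly. Evaluation of an assignment proceeds:

1. **Reassignment** of groups whose facility failed (above).
2. **Fleet allocation.** The formulation bounds only fleet totals, so the
   evaluator fixes a deterministic allocation: groups sorted severe-first,
   then by shortest trip time, then id; the global ambulance pool (and
   separately the helicopter pool) is dealt one vehicle at a time
   round-robin over groups still short of one vehicle per required trip
   (`⌈size/capacity⌉`). Blocked groups (big-M trips) get no vehicles.
3. **Shuttle dispatch.** A group with `v` vehicles and trip time `t` sends
   loads of up to the per-trip capacity; the k-th load (0-based) rides
   vehicle `k mod v` on its `a = ⌊k/v⌋+1`-th arrival, waiting `(2a−1)·t` —
   out-and-back round trips. Zero vehicles ⇒ big-M waits. Zero trip time
   (co-located points) ⇒ zero waits.
4. **Resource consumption.** Each arrival deducts its treatment cost
   (`C_r = 3`, `C_g = 2` units) from the facility stock. Severe casualties
   at a facility are charged before any minor ones, and once a severe
   casualty at a facility goes unserved no minor casualty is served there —
   leftover stock too small for a severe treatment is not diverted to
   minors, keeping the severe-first triage discipline exact. Unserved
   casualties are treated as big-M waits (death probability 1).
5. **Objective** `Σ batches size × P_death(state, wait)`. Per-batch waits by
   default; `group_wait="last_batch"` charges the whole group its final
   arrival, the more conservative single-wait reading.

The 30 h horizon is reporting metadata, not a hard constraint: no deadline
constraint exists in the formulation, and big-M waits already price
unreachability.

Monotonicity caveat: the objective is weakly increasing in ε within the
passable regime and flat in ε in the disrupted regime, but *crossing*
ε = 0.5 switches mode and can decrease travel time (helicopters are three
times faster than ambulances); the property tests therefore scale damage
within a regime.

## Robust counterpart

Casualty counts are interval-uncertain, `f̃ ∈ [f − f̂, f + f̂]` with
`f̂ = 0.2f` by default. For a candidate schedule with realized per-group
death probabilities `P`, the protection function

φ(Γ) = max over S ∪ {t}, |S| = ⌊Γ⌋ of `Σ_{i∈S} f̂_i P_i + (Γ−⌊Γ⌋) f̂_t P_t`

is a continuous knapsack, solved exactly by sorting the contributions
`f̂_i P_i` descending (ties by index). The dual certificate is the classical
one: `z* = ` the `(⌊Γ⌋+1)`-th largest contribution (0 past the end),
`p_i* = max(0, f̂_i P_i − z*)`, giving `Γz* + Σp* = φ` exactly; the tests
verify this identity, brute-force subset enumeration, and an independent LP
solve. Budgets are indexed per injury state by default (matching the usual
Γ_w sensitivity layout, each state's budget clamped to its number of
deviating terms); per-(point, state) budgets are supported, where each
singleton term deviates by `min(Γ, 1)`.

The robust objective is *evaluation-side*: nominal objective + summed
protection at the schedule's realized probabilities, and the solver
optimizes it as a black box. This mirrors how the model class is actually
solved (metaheuristically), avoids re-deriving the full MINP dual, and keeps
Γ=0 exactly equal to the nominal model. Protection sums globally across
points within a state; a per-point bound is available through
`per_point=True`.

## Solvers

Particles are integer vectors in `[1, k]^n`. Velocities update with inertia
`w = 1`, learning factors `c₁ = c₂ = 2`, and per-dimension uniform `r₁, r₂`;
positions are re-integerized after every move. Defaults: population 100,
300 generations, 10 independent runs with the minimum reported as the final
solution. Two numerical choices are the package's own:

* **Rounding**: half-up to nearest then clamp, rather than a literal
  ceiling — ceiling biases genes upward and makes facility 1 unreachable
  from positions in (0, 1). Ceiling is kept as `rounding="ceiling"`.
* **Velocity clamp** at `|v| ≤ k`, preventing runaway velocities that pin
  particles at the clamp bounds.

GA (binary tournament, one-point crossover at rate 0.8, per-gene reset
mutation at rate 1/n, elitism) and DE (rand/1/bin, F = 0.5, CR = 0.9, on
real vectors decoded by the same integerizer) are deliberately plain
baselines. `brute_force` enumerates up to 10⁶ assignments with
lexicographic tie-breaking. All solvers are deterministic given a seed
(per-run seeds derived from the base seed) and record monotone
per-generation best-value histories. A registry (`solvers.ALGORITHMS`)
accepts additional baselines.

## Synthetic instances

`GeneratorSpec` draws instances emulating a Lushan-earthquake-scale
emergency-rescue case: 9 affected × 7 medical points, fleet of 165
ambulances (50% of ~30 local + 50% of ~300 regional) and 15 helicopters,
capacities 2/4, speeds 40/120 km/h, costs 3/2, 30 h horizon, 20% count
deviations, and scenarios = one no-failure plus distinct single-facility
failures. Casualty ranges (severe 20–150, minor 40–300 per point) center
the per-point means near the case's treated head-counts; stocks 400–1,200
units put total capacity near total demand so resource scarcity binds
sometimes but not always; distances 5–60 km give 0.1–2 h ambulance trips,
the informative range of the mortality law. Damage degrees follow a mixture:
mass 0.5 intact, mass 0.1 disrupted (> 0.5), remainder uniform (0, 0.5].

`lushan_like_fixture()` is one fixed instance at that scale whose severe
(773) and minor (1,560) totals match the case's treated counts; its
per-point counts, distances, damage degrees and stocks are synthetic
stand-ins (the real per-point tables were never published), so
experiments on it reproduce the *structure* of the case study, not its
printed objective values. What passing tests show is therefore internal
consistency — exact arithmetic identities, oracle agreement, structural
invariants — not calibration against field data; real deployments would
need real casualty tables, road-state estimates and facility stocks.

## Problem sizes in the test battery

Solver-vs-oracle checks run on 3⁶–4⁶-assignment instances with
population 16–40 and 25–60 generations; the protection-function
enumeration covers 1,000 random lists of length ≤ 10; Monte-Carlo checks
use 10⁴ replicates. These sizes make every brute-force oracle exact while
keeping the whole battery in seconds, and are the package's reference
scale for regression testing; the case-scale fixture is exercised through
direct evaluation rather than full default-parameter solves.

## Known limitations

* Vehicles shuttle point-to-point per group; no multi-stop routing, no
  vehicle sharing across groups, no repositioning between facilities.
* No treatment queueing after arrival and no inter-hospital transfer;
  resources are a scalar stock per facility.
* Scenario aggregation is equal-weight (no scenario probabilities);
  the failure-aware planner optimizes the worst case by default, the mean
  optionally — which aggregation the field "should" use is left open.
* Uncertainty covers casualty counts only, not travel times or damage
  degrees, and the uncertainty set is the budget (cardinality) polytope,
  not ellipsoidal or distributional.
* Transition probabilities are time-invariant and triage is two-level.
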