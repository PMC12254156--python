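# Methods

## Model

`reaimsim` integrates a deterministic five-stock compartmental model of
program engagement with explicit fixed-step difference equations. The
stocks are head-counts (persons): `unaware`, `not_engaged`,
`not_initially_participating`, `participating`, `disengaged`. The
population is closed — no births, deaths or migration — so the five stocks
sum to `total_population` at every step, and the integrator preserves that
sum exactly (to floating-point round-off; the test suite asserts 1e-9
relative tolerance).

One step of length `dt = 1/steps_per_year` years proceeds as:

1. **Exposure.** `min(E·dt, unaware)` persons move unaware → not_engaged.
   Exposure is a constant flow (persons/year), not a proportional one; the
   clip prevents a negative stock once the unaware pool is exhausted, after
   which exposure is simply zero (there is no refill mechanism).
2. **Initial-reach split.** `not_engaged` is a one-step transit stock:
   everything present after the exposure inflow is split immediately, a
   fraction `p_initial_reach` to `participating` and the remainder to
   `not_initially_participating`. Because the split is a routing proportion
   applied to a transit cohort (not a dwell rate), the annual proportion is
   used directly, and `not_engaged` is always empty at recorded time points.
3. **Rate-driven outflows.** Delayed reach, disengagement and re-engagement
   move `q · source` persons, where the source stock is taken *at step
   start* (same-step inflows are not seen, which makes the update order
   immaterial and results bit-reproducible) and `q` is the per-step
   fraction equivalent to the annual effective fraction `p`:

       q = 1 − (1 − p)^(1/steps_per_year).

   This conversion is the semantic anchor of the model: the proportion
   parameters are *annual effective* fractions, so an isolated cohort under
   `p = 0.94` loses exactly 94% per model year at any step count. Naive
   division by the step count would deplete only ≈92%/year and break that
   reading. `p = 1` maps to `q = 1` (the whole source moves in one step) —
   the degenerate boundary of the sweep grid, handled without special
   cases.

Defaults: `total_population = 5000`, `exposure_rate = 150`/yr,
`steps_per_year = 12`, `horizon_years = 50` (600 steps), all four
proportions 0. The initial state places the entire population in `unaware`.
The scheme is an explicit fixed-step (Euler-style) difference-equation
update; no adaptive stepping and no randomness anywhere, so there is no
seed to manage.

## Cost model

Each support activity — initial reach, delayed reach, retention
(maintenance), re-engagement — has a unit activity cost that grows with the
ambition of the organisational target θ:

    c(θ) = base_cost · (e^{k·θ} − 1) / (e^k − 1)

with defaults `base_cost = 1` cost unit and steepness `k = 3` for every
activity. The normalisation pins `c(0) = 0` — an unsupported pathway
accrues nothing, which is what makes the no-support scenario strictly
cheapest — and `c(1) = base_cost`; the curve is strictly increasing and
convex between. Retention support uses the mirrored curve
`c(1 − p_disengage)`: a *low* tolerated disengagement is the expensive end.
The base costs and steepnesses are hypothetical and configurable; the
defaults were chosen once so the curves are visibly convex and the
qualitative cost orderings across scenarios are expressed, and they carry
no empirical calibration.

Accrual bases per step (using step-start stocks, matching the integrator):

- initial reach: event-based, `c(p_initial_reach)` per person crossing the
  initial-reach flow;
- delayed reach: `c(p_delayed_reach)` per person-year applied to the
  not-initially-participating pool;
- re-engagement: `c(p_reengage)` per person-year applied to the disengaged
  pool;
- retention: `c(1 − p_disengage)` per participant-year.

The stock-based (person-year) basis for the three ongoing supports reflects
support as a continuing service to the pool it targets rather than a fee
per successful transition; with per-transition charging the no-support
cheapness and cycling-cost results would persist, but per person-year is
the reading adopted here. Costs are undiscounted. Cumulative cost is the
component-wise sum of step increments, hence non-decreasing in time.

## Scenario engine

Four presets fix the two supported pathways: `no_support` (0, 0),
`enhanced_reach` (delayed reach 0.94), `reengagement_support`
(re-engagement 0.94), `both` (0.94, 0.94). For each, initial reach ×
disengagement is swept over an inclusive evenly spaced grid on [0, 1]
(default 21 points per axis; any resolution ≥ 2 is accepted, and 101 points
remains interactive). The sweep integrates all grid cells simultaneously as
numpy arrays using the same flow equations as the scalar stepper; the test
suite cross-checks the two paths cell by cell. Participation is read at the
final time point (year 50).

Two summary metrics support the qualitative claims:

- `dominance_ratio`: mean participation range across disengagement at fixed
  reach, divided by the mean range across reach at fixed disengagement.
  Above 1, disengagement is the dominant influence. A constant surface
  returns 1 by convention (no dominance either way); an exactly flat reach
  response returns infinity.
- `high_participation_cells`: the number of grid cells at or above a
  participation threshold.

### A structural note on cost surfaces

All four scenarios coincide exactly at the grid corner (reach = 1,
disengagement = 0): nobody ever occupies the not-initially-participating or
disengaged pools there, so the supported pathways are never exercised and —
by the `c(0) = 0` / empty-pool normalisation — never billed. That corner is
also the cost maximum of every scenario (maximal retention support applied
to a full participant pool for 50 years), so the scenarios' grid *maxima*
tie while their grid *means* order strictly: no-support cheapest, both
supports costliest. Scenario comparisons of "overall" cost in the package
therefore use the grid mean, with the max compared non-strictly.

Similarly, total cost at full reach is U-shaped in disengagement: near
d = 0 the retention support itself is the dominant expense; as d grows the
cycling of participants through the supported re-engagement loop takes
over. The cycling claim is therefore tested on its mechanism — the
re-engagement cost component increases monotonically with disengagement at
full reach, and the supported scenario's total exceeds the unsupported
one's at every positive disengagement — rather than as full-range
monotonicity of the total, which the retention curve rules out.

## Interfaces

Configuration is a flat YAML file (all keys optional, unknown keys
rejected, range errors name the offending key). Trajectories and sweeps
serialise to CSV with frozen column names and deterministic row order
(byte-identical across reruns); a run summary serialises to JSON; heatmaps
(participation and cost panels per scenario, shared colour scale per
outcome) are optional PNG outputs that degrade to a warning if the
rendering backend is unavailable. The `reaimsim` console script exposes
`run`, `sweep` and `presets` subcommands; exit codes are 0 (success),
1 (validation error), 2 (I/O error).

## Scope and limitations

- Cohort-level dynamics only: every disengaged person has the same
  re-engagement likelihood regardless of how often they have cycled before.
  Capturing habituation or fatigue needs individual-level (agent-based)
  memory, which is outside this model class.
- Program effectiveness, adoption and downstream health outcomes are held
  constant and not modelled; no cost-effectiveness ratios or QALYs.
- The cost parameters are hypothetical units; surfaces support qualitative
  comparison between strategies, not budgeting.
- Exposure halts when the unaware pool empties; there is no population
  turnover reintroducing unaware persons.
- Fixed-step explicit integration matches the monthly-update design; it is
  not an exact continuous-time solution, though the annual-effective-rate
  conversion makes whole-year cohort depletion exact by construction.
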