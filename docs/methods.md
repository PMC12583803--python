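# Methods

This note documents the model implemented by `dmocea`: its structure,
assumptions, parameter conventions, synthetic stand-ins, numerical
choices and known limitations. It is the package's own account; every
number quoted here is computed by the code or carried in the bundled
parameter registry.

## Cohort model

The population is a cohort entering at age 63 (58% male) with
centre-involving diabetic macular oedema and CRT ≥ 400 µm. Health states
are eight 10-letter BCVA bands for the treated (study) eye — >85 down to
≤25 ETDRS letters — plus an absorbing death state. Cycles are 3 months;
the horizon runs to age 100 (configurable); costs and QALYs are
discounted at 3.5% per year with per-cycle factors evaluated at the cycle
midpoint, `(1 + r)^(−(c + 1/2)·Δt)`.

Movement between bands is limited to one band per cycle, reflecting an
"average eye" interpretation of a 5–15-letter change: a state move
requires crossing half a band (±5 letters). Within a cycle, mortality is
removed first as a competing hazard; survivors then move under the
strategy's alive-conditional kernel. All kernels are validated to be
row-stochastic (1e−12), tridiagonal among alive states, with death
absorbing.

### Transition kernels

* **Natural history** — per-cycle gain/stay/lose probabilities
  3.5% / 92.0% / 4.5% (WESDR recalibrated against RESTORE). Boundary
  bands fold the impossible move into "stay". The no-treatment arm uses
  this kernel for its entire trajectory, always.
* **Treatment effect** — each active strategy has a 12-month mean BCVA
  difference vs no treatment (logMAR; network meta-analysis), converted
  at 1 letter = 0.02 logMAR. Assuming an individual's BCVA change over a
  cycle is Normal with mean `letters × Δt` and standard deviation
  `σ_annual × √Δt`, the per-cycle probabilities of moving one band are
  the tail masses beyond ±5 letters. `σ_annual` has no published value;
  the default of **10 letters** (5 letters per quarterly cycle) is a
  design parameter exposed in `ModelConfig.sigma_letters_annual` and
  flagged prominently: it controls how sharply mean effects separate the
  arms' transition probabilities.
* **Effect delivery over time** — the NMA difference is a 12-month
  contrast, so the effect-derived kernel is applied during model year 1
  only. While the effect persists (base case: lifetime), the cohort then
  *holds its achieved BCVA* (identity kernel among alive states); natural
  history resumes only when persistence ends (cessation scenarios at 5,
  10 or 20 years). This is the single most consequential modelling
  choice. Continuing to apply the improving kernel beyond year 1 would
  compound the 12-month contrast indefinitely; reverting to natural
  history immediately would contradict the observation that
  discontinuation is dominated by stable disease. Both alternatives
  remain available via `ModelConfig.effect_mode`
  (`maintenance` | `continued-effect` | `natural-history`).
* **Mortality** — annual life-table probabilities, sex-mixed at the
  cohort's male fraction and looked up at the integer age floor, are
  converted to hazards, scaled by the diabetes hazard ratio (1.95,
  lognormal(µ=0.668, σ=0.090) in the PSA) and by the cycle fraction,
  then converted back to a probability. Ages advance 0.25 years per
  cycle.

### Eyes, utilities and QALYs

At baseline 22% of the cohort is treated in both eyes; of the one-eye
remainder, 67.2% are treated in the worst seeing eye (WSE) and 32.8% in
the best seeing eye (BSE). Each cycle, 5.4% of one-eye members develop
fellow-eye disease and convert to the both-eyes configuration, switching
both their cost basis (drug doubled) and their utility column.

Utilities attach to the treated eye's BCVA band: the BSE column (0.860
down to 0.547) applies to BSE-treated and both-eyes members (the better
eye drives quality of life); the WSE column applies to WSE-treated
members and declines linearly from 0.860 to a floor of 0.760 (total
decrement 0.1). Death has utility 0. QALYs accrue as
`Δt × ½(u_start + u_end)` per cycle (trapezoidal half-cycle correction),
minus expected one-off adverse-event disutilities, all discounted.

### Treatment continuation, costs

Everyone remains on treatment through year 1. Strategy-specific annual
discontinuation hazards apply from year 1; from year 3 the fixed
continuation fractions multiply alongside them — 75% during years 3–5 and
50% thereafter (scenario levers 25%/75%).

Per-cycle costs, scaled by occupancy and on-treatment fraction:

* drug (and laser-session) cost × administrations, doubled for the
  both-eyes fraction;
* anti-VEGF administration at £257.981 per injection visit — the
  weighted sum OCT £101.804 + 95% × outpatient £129.616 + 5% × day-case
  £660.838 — with both eyes treated in one visit; laser administration is
  folded into the laser treatment cost;
* monitoring: treatment is delivered at monitoring visits, so only
  monitoring visits in excess of injection visits are charged (at
  £101.804) unless the separate-visit scenario is active; discontinuers
  are monitored indefinitely at the post-treatment tariff (£38.344),
  2 visits/year by default;
* low vision: £421.609 per cycle for occupancy in the two lowest bands
  (BCVA ≤ 35 letters);
* adverse events: expected one-off costs per cycle on treatment;
* subsequent treatment: members discontinuing within the last 2 years
  accrue the weighted per-cycle cost of their switch target's first-year
  schedule.

Recurring items (monitoring, low vision) use the trapezoidal occupancy
average; one-off items (injections, adverse events, subsequent
treatment) use start-of-cycle occupancy and are not half-cycle
corrected.

## Economics

Each strategy is compared with no treatment only (no incremental
frontier): ICER = ΔC/ΔE with dominance flags for degenerate quadrants,
and NMB = λE − C at £20,000 (primary), £25,000 and £30,000 per QALY.
Rankings sort by NMB descending with ties broken by lower cost then
name. Currency is reported to whole pounds; internal arithmetic is
unrounded.

## Probabilistic sensitivity analysis

Every registry entry carries a distribution: beta for probabilities and
utilities, gamma for costs (the printed cost gammas share shape 96.036,
with scale reproducing each printed mean), normal for treatment effects,
lognormal for the mortality hazard ratio, Dirichlet for the baseline
BCVA distribution, the eye split and the natural-history triple.
Dirichlet concentrations are `proportion × ESS` with ESS = 100
(a weakly informative default; zero-proportion states receive ε = 1e−6
to keep the simplex support intact). Synthetic quantities without
published dispersion get SD = 10% of the mean (±20% ≈ ±2 SD).

One coherent draw per iteration is applied to **all** strategies (common
random parameters), the weighted administration cost is recomputed from
its sampled components, and the deterministic engine is re-run. Draws
use a single `numpy` generator seeded from the run seed, so results are
bit-reproducible. Treatment effects are sampled independently across
arms (the NMA covariance is not available) — incremental comparisons
between active arms therefore overstate effect-difference uncertainty;
comparisons with no treatment are unaffected. Sampled utility columns
are not re-sorted, so monotonicity across bands can be violated within a
draw; with the bundled concentrations this is rare and unbiased.

Under these synthetic conditions the probabilistic rank-1 frequencies
concentrate on the four cheap strategies (both lasers, bevacizumab, no
treatment) with no treatment modal: the natural-history Dirichlet at
ESS = 100 is dispersed enough that a material share of draws has
gain > lose, in which case the untreated cohort drifts upward for life
while treated arms hold achieved vision. This is a consequence of the
deliberately weak Dirichlet prior and the maintenance assumption, and it
is much weaker in the deterministic base case, where the published
ordering is reproduced exactly.

## Scenario analyses

Eight scenarios each move exactly one configuration lever from the base
case: effect persistence 20/10/5 years; continuation after year 5 at
25%/75%; monitoring costed in a separate visit from treatment; and
minimum/maximum monitoring-and-treatment intensity (±2 visits and ±2
injections per schedule year, floored at zero — synthetic bounds, since
the published bounds are not available). Scenario reports are
deterministic by default with an optional PSA flag.

## Synthetic stand-ins

Two input families are not publicly available and are generated by
`dmocea.synthetic`, flagged `is_synthetic` throughout:

* **Life table** — Gompertz–Makeham hazard `c + a·e^{b·age}` with
  a = 3e−5, b = 0.095, c = 5e−4 and a symmetric male/female hazard gap of
  1.4, closed out at age 110. This yields qx(63) ≈ 0.012 and a remaining
  life expectancy in the realistic range for the entry cohort; it does
  not reproduce any national table's exact values.
* **Supplementary treatment inputs** — injection schedules (anti-VEGF:
  8, 5, 3, 2, 2… per year, mirroring loading-dose practice), monitoring
  schedules, laser sessions (2, 1, 0; shared by all combination arms),
  adverse-event profiles (per-cycle probabilities ≤ 0.5% with one-off
  costs and disutilities), discontinuation hazards (anti-VEGF
  0.10/0.10/0.05; laser 0.20/0.15/0.05 per year), and
  subsequent-treatment weights. Switches never stay within a therapeutic
  class: anti-VEGF and combination discontinuers move to standard laser;
  laser non-responders are rescued with bevacizumab, the cheapest
  cost-effective anti-VEGF in the UK pathway. Sharing rules mirror the
  model's stated equivalences (biosimilar ↔ originator resource use;
  bevacizumab+laser ↔ ranibizumab+laser resource use but bevacizumab's
  adverse events; subthreshold ↔ standard laser efficacy and adverse
  events).

Because these are stand-ins, passing tests demonstrate the *mechanics*
and the qualitative economics of the model — orderings, identities,
invariants — not agreement with the published absolute totals. The
deterministic QALY separations between arms are roughly half the
published ones, and absolute costs differ; the qualitative pattern (all
anti-VEGFs above both lasers above no treatment in QALYs; lasers with
the lowest ICERs; bevacizumab the best anti-VEGF by NMB; the top-three
NMB set {bevacizumab, standard laser, subthreshold laser}) is
reproduced. Replacing the synthetic CSVs with real inputs of the same
schema requires no code changes.

## Numerical choices and degenerate inputs

* Row-sum tolerance 1e−12; occupancy conservation checked at 1e−10 per
  run.
* The engine and a matrix-power closed form agree to 1e−10 on toy
  chains; the normal-model transition probabilities agree with numerical
  integration of the density to 1e−8.
* `p_gain + p_lose ≤ 1` holds automatically (disjoint tails);
  constructors reject negative probabilities, σ ≤ 0, and
  `horizon ≤ start age`.
* The terminal life-table age forces qx = 1 regardless of hazard-ratio
  scaling.
* Registry CSV round-trips are bit-exact (floats serialised via `repr`).
* Problem sizes in the test suite and acceptance script are chosen to
  keep full runs fast: 148 cycles per projection, PSA moment checks at
  n = 10⁴ draws of the samplers, model-level PSA checks at 150–200
  draws, 3-standard-error Monte-Carlo tolerances.

## Limitations

* One-eye model: health states track the treated eye only; fellow-eye
  involvement affects costs and the utility column, not a joint
  two-eye BCVA state.
* Cohort (not individual-level) simulation: no heterogeneity in
  treatment response or discontinuation beyond the cohort fractions.
* Synthetic supplementary inputs and life table (above); confidential
  discount prices are representable only through the configurable price
  hooks.
* Independent effect draws across arms in the PSA.
* No proliferative-retinopathy state; its impact is assumed embedded in
  the BCVA transitions.
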