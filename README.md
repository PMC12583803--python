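# dmocea

Lifetime cost-utility modelling of treatments for **centre-involving
diabetic macular oedema (CI-DMO)** with central retinal thickness
≥ 400 µm, from the perspective of the UK NHS.

Diabetic macular oedema is a leading cause of vision loss in people with
diabetes. For the severe (CRT ≥ 400 µm) subgroup, clinicians choose among
intravitreal anti-VEGF agents (aflibercept, bevacizumab, brolucizumab,
faricimab, ranibizumab and its biosimilar), macular lasers (standard
threshold and subthreshold micropulse), combinations, and no treatment.
`dmocea` is for health economists and HTA analysts who need a transparent,
testable implementation of the decision model behind that comparison:
eleven strategies evaluated in a single cohort framework with full
probabilistic and scenario analysis.

## The model

A **Markov cohort model** with nine health states — eight best-corrected
visual acuity (BCVA) bands (>85, 76–85, …, ≤25 ETDRS letters) and death —
evolves a cohort (entry age 63, 58% male) in 3-monthly cycles with a
half-cycle correction, discounting costs and QALYs at 3.5% per year.
Movement is limited to one BCVA band per cycle:

- **Natural history** (no treatment): per-cycle probabilities of gaining /
  staying / losing one band of 3.5% / 92.0% / 4.5%.
- **Treatment effects**: 12-month mean BCVA differences vs no treatment
  (logMAR, from a network meta-analysis) are converted to letters
  (0.1 logMAR = 5 letters) and to per-cycle band-transition probabilities
  by assuming individual BCVA change X ~ N(µ·Δt, σ²·Δt) and reading off
  the tail masses beyond the ±5-letter band boundary:
  p_gain = P(X ≥ 5), p_lose = P(X ≤ −5).
- **Mortality**: age/sex life-table hazards scaled by the diabetes hazard
  ratio HR = 1.95 on the hazard scale,
  p_death = 1 − exp(−HR · Δt · (−ln(1 − qx))).
- **Economics**: per-strategy injection/monitoring/laser schedules, a
  weighted anti-VEGF administration cost of £257.981 per injection visit,
  low-vision costs of £421.609 per cycle for BCVA ≤ 35 letters,
  BCVA-band utilities (best- vs worst-seeing-eye columns), treatment
  discontinuation (everyone treated in year 1; 75% continue in years 3–5,
  50% thereafter, alongside strategy-specific hazards), fellow-eye
  involvement, adverse events and subsequent treatment.

Each strategy is compared with no treatment:
ICER = ΔC/ΔE, and **net monetary benefit** NMB = λ·E − C at
λ = £20,000/£25,000/£30,000 per QALY; the highest-NMB strategy is the most
cost-effective. A probabilistic sensitivity analysis samples every
parameter from its declared distribution (beta, gamma, Dirichlet, normal,
lognormal); eight deterministic scenario analyses vary effect persistence,
long-term continuation, visit structure and schedule intensity.

Inputs the published evidence base does not report — national life tables
and supplementary schedules/adverse-event/discontinuation tables — are
replaced by clearly flagged synthetic stand-ins (`dmocea.synthetic`),
so the full pipeline runs with no downloads. See `docs/methods.md`.

## Worked example

```python
from dmocea import CostUtilityModel

model = CostUtilityModel()          # bundled registry + synthetic inputs
results = model.fit()               # deterministic lifetime projection
print(results.summary())
```

```
Deterministic lifetime cost-utility results (discount 3.5%, horizon age 100)
============================================================================
                                            Strategy  Cost (GBP)  QALYs ICER vs no treatment  NMB at 20,000  Rank
                            Standard threshold laser        5276  8.649               15,172         167698     1
                       Subthreshold micropulse laser        5298  8.649               15,264         167676     2
                                         Bevacizumab        7979  8.782               17,003         167663     3
           Bevacizumab plus standard threshold laser        8418  8.784               18,099         167260     4
                                        No treatment        1675  8.411                    -         166552     5
                    Ranibizumab biosimilar (Ongavia)       21890  8.795               52,729         154005     6
                              Ranibizumab (Lucentis)       22700  8.795               54,843         153194     7
Ranibizumab (Lucentis) plus standard threshold laser       23161  8.784               57,685         152515     8
                                         Aflibercept       30450  8.839               67,297         146329     9
                                        Brolucizumab       30451  8.838               67,427         146312    10
                                           Faricimab       31645  8.852               67,945         145404    11
```

Reading the table: every anti-VEGF produces more QALYs than either laser,
which in turn beat no treatment; but the lasers' very low cost gives them
the lowest ICERs versus no treatment, and bevacizumab is the most
cost-effective anti-VEGF (at list prices). Probabilistic and scenario
analyses hang off the same object:

```python
psa = model.fit_psa(n_draws=1000, seed=7)      # PSAResult
psa.summary_frame(); psa.rank_frequencies()
scen = model.fit_scenarios()                   # 8 scenarios + base
scen.top_three["base"]
# ['laser_standard', 'laser_subthreshold', 'bevacizumab']
```

A command-line interface mirrors the library:

```sh
dmocea validate                  # registry invariant checks
dmocea --out out run             # deterministic results table (CSV/JSON)
dmocea --seed 7 psa --n 1000     # probabilistic analysis
dmocea scenarios                 # scenario suite
dmocea synth                     # emit synthetic life table + inputs
```

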