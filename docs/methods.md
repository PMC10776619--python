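# Methods

## Model structure

`brcascreen` is a deterministic compartment model evaluated in expected
counts, with a Monte Carlo microsimulation as its stochastic
counterpart. Each generation is a fresh steady-state cohort of
`N = 274,000` women entering at age 18 and followed to age 80 (one
62-year cycle). Within a generation the flow is:

1. **Carriers.** `C = N·π` expected BRCA1/2 pathogenic-variant carriers
   (central π = 0.67 %).
2. **Selection for genetic testing.** Clinical criteria / family
   history select `N·e` women (central e = 0.98 %), of whom 10 % are
   carriers; a carrier's clinical detection probability is therefore
   `r_clin = N·e·0.10/C ≈ 0.146`. Models 2/3 additionally screen with a
   radiogenomic ultrasound classifier (sensitivity/specificity 0.49/0.87
   and 0.80/0.95). Adherence to offered testing is 100 % by design.
3. **Detection.** Generation 1 combines the channels by union:
   screening detects `C·se`, clinical criteria add the screen-negative
   eligible carriers `r_clin·C·(1−se)`. In generations ≥ 2 cascade
   testing detects `C·f` (f = previous generation's awareness fraction)
   and, while screening is offered, the residual `C(1−f)` is picked up
   at the additive rate `min(1, se + r_clin)`. Once screening is
   withdrawn (generation 3) the residual is left to cascade alone; a
   configuration switch (`residual_rule_inactive="clinical"`) restores
   clinical pickup of the residual instead. The additive residual rate
   (rather than a union) and the cascade-only withdrawal rule are what
   the published generation 2/3 compartments imply; both choices are
   selectable per run.
4. **Surgery and cancers.** Detected carriers choose a
   prophylactic-surgery stratum (central: both 25.85 %, RRSO only
   29.15 %, RRM only 21.15 %, none 23.85 %); each stratum has a lifetime
   cancer-risk row (breast only / ovarian only / both / none).
   Undetected carriers face the no-surgery row (central cancer
   probability 0.795 vs 0.379 mix-weighted). Cancer onset is a point
   event at the scenario's single average onset age (central 45); there
   is no cancer mortality, no per-age incidence curve and no competing
   risk — the endpoint is BRCA-cancer-free life years.
5. **Life years.** Healthy life-years lost = cancers × (80 − onset age),
   without disability weights, age weighting or discounting. This linear
   accounting is what the source's "DALY" rows implement (their ratio to
   the cancer rows is exactly the onset-to-exit span), so outputs are
   labelled `hly_lost (DALY)`.
6. **Awareness carryover.** End-of-cycle awareness = detected carriers +
   carriers diagnosed at cancer onset; its fraction of `C` seeds the
   next generation's cascade. Model 1 carries no cascade memory (its
   published results are a single generation-invariant column); a flag
   (`model1_cascade`) enables it for exploration.

## Parameters

All inputs live in `ScenarioParameters` (three built-in columns:
central / best / worst, also shipped as `data/*.yaml`). Probabilities
are fractions; costs are euros (Italian DRG tariffs, no discounting or
inflation adjustment); ages/durations are years. Probability blocks
must sum to 1 within 1e-9; blocks off by up to 0.1 % (the printed
best-case no-surgery row sums to 100.02 %) are renormalized with a
logged warning. The stated prevalence-in-not-eligible rate (0.58 %) is
not used in the arithmetic — it is implied by the other three rates —
and is retained only for a consistency warning. The screening
performance of model 2 defaults to the published 49 % sensitivity; the
results-table header variant (47 %) is reachable via `ModelConfig`.

## Costs

Five components per model × generation, assembled by an explicit,
configurable rule ledger (`CostRules`), since the exact assignment
rules are supplementary material not available to this implementation:

* testing: 1,099.48 EUR per woman eligible for testing;
* screening visit: 51.65 EUR (gyn visit + US) per screened woman
  (`N(1−e)`) in screening-active generations. Default is to bill it;
  with it the model reproduces the published cost increments and ICERs
  closely (e.g. +2.54 vs +2.51 EUR/year/person, ICER 3,849 vs 3,799.98
  for model 2 generation 1), while treating the screen as free routine
  care would make model 3 cost-saving already in generation 1;
* prophylactic surgery: mix-weighted RRSO (1,436)/RRM (1,960) tariffs
  per detected carrier (central expectation 1,711 EUR);
* treatment: ovarian-involved cases 6,791 + 2,226 + 82,344 EUR
  (surgery, chemotherapy, PARP-inhibitor therapy — assigned to all
  ovarian-involved cases by default, restrictable by `parp_fraction`);
  breast-involved cases 3,524.45 + 2,226 + 6,000 EUR (mastectomy,
  chemotherapy, radiotherapy); both-cancer patients incur both bundles;
* follow-up: 198.20 EUR/year for known carriers over the whole cycle,
  69.60 EUR/year otherwise; carriers diagnosed at onset switch rates at
  the onset age. Indirect/societal costs are out of scope.

Absolute cost levels are therefore tolerance-level reproductions, not
cent-exact ones; the model-1 total lands at 73.85 vs the published
73.80 EUR/year/person.

The eligible-for-testing counts in generations ≥ 2 are structurally
derived from the same channel logic (cascade carriers plus residual
screen/clinical channels; after withdrawal,
`C·f + (N·e − r_clin·C)(1−f)`); the published counts follow
supplementary assumptions and differ by a few percent in screening
generations, so these counts — and the testing costs built on them —
are approximate by construction.

## Scenario columns

Best and worst columns are taken at face value from the input table,
including their surgery-uptake and post-surgery risk rows. One
consequence is worth stating: the worst column pairs its higher
prevalence with much lower surgery uptake (36.3 % no surgery) and
higher post-surgery risks, which shrinks the prevention gained per
detected carrier (0.247 vs 0.416 cancer-probability reduction
centrally). Under these inputs the worst-case generation-1 ICERs come
out above the central ones, i.e. screening buys *less* health per euro
in the worst column, not more; the published scenario ICER ordering
(worst < central < best) is not recoverable from the main-text inputs
and the corresponding checks in the acceptance suite document this
divergence rather than hide it.

## Microsimulation

The microsimulation draws each woman independently: carrier status
~ Bernoulli(π); eligibility with carrier-dependent rates reverse-
engineered from the marginals (`P(eligible|carrier) = r_clin`,
`P(eligible|non-carrier) = (N·e − r_clin·C)/(N − C)`) so expectations
match the cohort engine exactly; screening per sensitivity/specificity;
surgery and cancer outcomes multinomial per stratum row. Cascade
generations reuse the cohort awareness fraction as a per-carrier
Bernoulli probability of an aware relative — no pedigree graph is
simulated. The cohort engine's additive residual rule is realized as a
single Bernoulli draw at `min(1, se + r_clin)`; independent channel
draws would OR to `se + r_clin − se·r_clin` and systematically
undershoot it. Replicate seeds are spawned deterministically from one
root seed (`numpy.random.SeedSequence`); every entry point requires an
explicit seed and identical seeds give bit-identical output.

What passing validation shows — and does not. Agreement of replicate
means with the cohort expectations (within 3 Monte Carlo standard
errors, 100 replicates at full cohort size run in seconds) verifies
that the deterministic engine computes the expectations of the stated
stochastic process. It does not validate the process against real
populations: real eligibility clusters in families, screening
performance varies with age and machine, surgery uptake depends on age
and parity, and onset ages are distributed, none of which the generator
emulates.

## Numerical choices

All compartment arithmetic is carried at full precision; rounding (half
away from zero: integers for counts, 2 decimals for euros, 1 for
percentages) happens only in display tables and reports. Detection is
capped at `C` after the additive rule, scaling routes proportionally.
An ICER with zero health-gain denominator is reported as undefined with
a flag, never as infinity. Degenerate inputs (zero prevalence, zero
positivity) short-circuit to zero compartments rather than erroring,
except where a rate is genuinely undefined (`clinical_detection_rate`
with zero carriers raises).

## Limitations

Cohort-level cascade (no pedigrees), single onset age, no mortality or
competing risks, no testing-uptake shortfall (100 % adherence by
design), no variants of uncertain significance, no indirect costs, no
discounting, and scenario analysis restricted to the three discrete
input columns (no probabilistic sensitivity analysis).
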