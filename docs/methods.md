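# Methods

This note documents the model as implemented: its assumptions, parameters,
numerical choices, what the synthetic data do and do not emulate, and the
design decisions taken where the design was genuinely open.

## State space and cycle structure

Six states: CVD-free, post-CHD, post-CBVD, and three absorbing death states
(fatal CVD as first event, non-CVD death from the CVD-free state, and
all-cause death after a non-fatal event). Chronic states are reachable only
from CVD-free; recurrent events inside the chronic states do not create new
states — they add costs and utility decrements in the cycle they are
expected to occur.

Cycles are one year, with **no half-cycle correction**: events are assigned
at cycle end, so accrual in a cycle uses start-of-cycle occupancy. A person
who has an event during cycle *t* accrues CVD-free utility and costs in
cycle *t* and enters the chronic state at cycle *t* + 1 with
time-since-event 0. The simulation runs to age 110, a lifetime-horizon
proxy; residual alive occupancy at that age is negligible under the default
mortality (and those cycles are excluded from accrual rather than
extrapolated).

The trace is a deterministic expected-value propagation per individual, not
a stochastic walker simulation. Parameter uncertainty is handled at the
parameter level by the PSA; keeping the traces deterministic means
first-order Monte Carlo noise cannot contaminate incremental ratios.
Chronic-state occupancy is resolved by entry cycle (a per-individual
triangle), because post-event mortality, recurrent-event probability, and
post-event costs all depend on age at event and time since event.

## Hazards

First events use four competing cause-specific Gompertz hazards
`h_k(t) = exp(β_k·x)·exp(γ_k t)`. The time scale is years since model entry
(configurable to age), with attained age entering through the age covariate,
updated each cycle. The cycle split
`p_k = (H_k/H)(1 − e^{−H})`, `stay = e^{−H}` is exact when the
cause-specific hazards are proportional over the cycle; the bundled
transition models share one shape per state, so the engine operates in the
exact regime, and the oracle tests generate fixtures in that regime. The
cumulative hazard uses the closed form
`λ(e^{γt₁} − e^{γt₀})/γ` via `expm1`, with a first-order series below
`|γ| < 1e−8` to avoid cancellation; agreement with adaptive quadrature is
better than 1e−10 and the γ→0 limit matches exponential rates to 1e−8.

Post-event mortality is all-cause Gompertz on time since event with
covariates age at event, SIMD, and family history. Recurrent events use a
probit `Φ(β·x)` on the same covariates, constant over time since event.

## Treatment

A strategy's non-HDL-c reduction is applied to each individual's TC − HDL;
relative risks per 1.0 mmol/L map the absolute reduction onto the three
CVD first-event transitions log-linearly (`RR^Δ`). Multipliers act on first
events only (primary prevention); post-event management is unchanged. The
HDL-raising effect of treatment shifts the HDL covariate in post-treatment
linear predictors (option `apply_hdl_shift`, default on — this is what makes
the HDL parameter consequential in the tornado analysis). Adherence is full
and lifelong; there is no discontinuation model.

The diabetes side effect is an expected annual cost: absolute risk increase
× annual diabetes treatment cost (£314.33), charged (or credited, for
berberine's negative ARI) every treated alive year, with no feedback into
the CVD hazards. Pill-taking disutility (0.002 QALY/yr) is subtracted from
the utility of every treated alive year before clipping to [0, 1].

Costs charged to a treated individual: risk assessment £17.68 once at entry,
drug cost + monitoring (first-year £102.51, subsequent £55.48) while alive,
plus the diabetes term. Screening is charged in active intervention arms
only, so the treated-minus-untreated cost difference under a zero-effect
intervention equals the discounted treatment stream exactly — a conservation
property the tests assert to 1e−9. (Charging assessment to the comparator
too is a one-line config change; it cancels from every increment.)

## Utilities and costs

Baseline utility is linear in sex and (attained age − 40) with a small
quadratic term; chronic states subtract an event-specific decrement, and
each expected recurrent event subtracts a further decrement in its cycle.
Utilities are clipped to [0, 1] per state per cycle, and cycle QALYs floored
at 0. QALYs ≤ life-years holds by construction.

Annual costs come from two regressions with natural cubic spline time
trends: pre-event (function of time in model, age at entry, SIMD, family
history) and post-event (function of time since event, age at event, SIMD,
family history; the spline's high value at time 0 represents the acute
admission year, decaying to a chronic management level and rising again late
with age). Evaluated costs are clipped at 0. Life-years are reported
undiscounted; QALYs and costs discounted at 3.5%/yr (`1/(1+r)^t`, year 0
undiscounted).

## Synthetic cohort

The generator reproduces the *marginal* structure reported for the eligible
pool: 55.6% women; women with lower mean SBP, higher mean TC, higher mean
HDL-c than men. Continuous covariates are truncated normals per sex
(inverse-CDF sampling, so an optional Gaussian copula over age/SBP/TC shares
the code path; default independent), cigarettes/day a zero-inflated count,
SIMD uniform over its score range. TC is truncated below at HDL + 0.1 per
row, so `hdl < tc` holds by construction. Statin users and prior-CVD cases
are assumed already excluded. Exact summary statistics of the real eligible
population live in unpublished supplementary material; the defaults are
plausible values for a risk-assessed Scottish population aged 40+ and are
documented in `cvdcea.cohort.DEFAULT_GENERATOR_CONFIG`.

What the generator does **not** emulate: survey weights and design effects,
joint dependence beyond the optional three-way copula, secular trends, and
measurement error. Passing tests therefore demonstrate correctness of the
machinery and the robustness of the incremental pattern — not calibration of
absolute event counts, QALYs, or costs to the real population.

## Placeholder coefficients and calibration

The ASSIGN score coefficients and the Gompertz/probit/utility/cost
regression tables are inputs to this model, published in supplementary
tables of the source model and not redistributable here. The bundled
`coefficients.yml` is flagged `provenance: placeholder` and the loader warns
whenever placeholders are active. The placeholders were calibrated once, as
a design choice, so that:

* the synthetic pool's eligible fractions land near 34.4% (risk ≥ 20%) and
  60.0% (risk ≥ 10%) — achieved by scaling the ASSIGN linear predictor and
  choosing the per-sex centering constants against a 20,000-person reference
  draw;
* first-event and mortality rates are realistic for a Scottish risk-assessed
  population (e.g. ~1%/yr non-fatal CHD hazard for a 65-year-old male
  smoker-adjacent profile, non-CVD mortality consistent with a Gompertz-like
  age gradient);
* post-event prognosis and costs have conventional magnitudes (~5–7%/yr
  initial post-event mortality rising with time since event; acute-year
  costs of £3–4k decaying to sub-£1k chronic management).

Under these conditions the headline qualitative pattern is stable across
generator seeds: all four active strategies cost-effective at £20,000/QALY
against no intervention, berberine dominated by the statin at Scottish
prices, not dominated at Chinese prices. Replacing the placeholders with the
published tables (and setting `provenance: published`) is the supported path
to absolute-level results.

## Uncertainty analysis

**Distribution fitting.** Each Table-style row (base case + 95% CI + family)
is fitted by moment matching with sd = CI width / 3.92: beta on the
proportion scale, gamma by shape/scale moments, log-normal by matched
meanlog/sdlog. Negative-support rows (berberine's protective diabetes ARI)
are fitted on the negated scale and negated back on sampling. Where the
printed CI is too asymmetric for a two-parameter moment fit to reproduce it
(relative deviation above 5%, measured against max(|endpoint|, CI width)),
the fit is refined using the family's support transform: shape plus shift
solved so the mean stays exact and both CI endpoints match (heavily skewed
cost rows such as the berberine price become shifted gammas). The
combined-therapy diabetes ARI (base 0.0 over −4.6…0.5) cannot be a
log-normal; it is fitted as a mean-preserving scaled beta over a support
solved from its CI — the one family deviation, chosen to keep the
law-of-large-numbers property (draw means converge to the base case) true
for every parameter.

**PSA.** Each iteration draws every uncertain parameter once (shared across
strategies), rebuilds the parameter set, and re-runs the deterministic
pipeline for all strategies on the identical cohort. Iteration *i* uses the
*i*-th spawn of `SeedSequence(seed)`, so runs are reproducible and
individual iterations are independent. By default only the intervention
table parameters are sampled; survival-regression coefficient resampling is
available behind `sample_coefficients` but off, since placeholder standard
errors would only add noise. Base-case (no-intervention) outcomes are
constant across iterations and computed once.

**CEAC.** At each willingness-to-pay λ the probability that a strategy
maximises net monetary benefit λ·Q − C among all compared strategies, ties
split equally — probabilities sum to one at every grid point. Pairwise
quantities against a single reference are available via `psa_increments`.

**Tornado.** Each parameter alone is set to its CI endpoints (discount rate
to its configured 1.5–5.5% range), the headline ICER recomputed, rows sorted
by range. Parameters that cannot affect the chosen comparison are excluded
rather than reported as zero rows.

## Problem sizes

Defaults were chosen so a full analysis is interactive on one CPU: the
bundled examples and tests use cohorts of 40–500 (full pool 3,869 for
eligibility fractions), and the acceptance script runs a 500-person lifetime
simulation at both price settings plus a 200-iteration PSA. The engine is
vectorised over individuals; a 1000-iteration PSA on a 500-person cohort
takes a few minutes.

## Known limitations

* Placeholder regression tables: absolute levels are illustrative by design.
* No treatment discontinuation, titration, or dose–response interpolation;
  no statin-intolerance switching.
* Fatal CVD after a non-fatal event is not split from other causes (single
  death-after-event state), matching an all-cause post-event mortality
  model.
* Costs are GBP at the config's price year with no inflation adjustment; no
  societal-perspective costs.
* The "any CVD" relative risk is stored but unused — the three
  transition-specific RRs drive the model.
* CHEERS-style reporting artefacts (tables, plots) are minimal plain
  matplotlib/CSV outputs.
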