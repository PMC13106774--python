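# cvdcea

Lifetime cost-effectiveness modelling of lipid-lowering strategies for the
**primary prevention of cardiovascular disease (CVD)** in a risk-assessed
adult population: no intervention, a statin (atorvastatin 20 mg/day),
berberine (1000 mg/day, a nutraceutical), and two fixed-dose
statin + berberine combinations. It is written for health-economic modellers
and epidemiologists who want a tested, scriptable implementation of this kind
of policy model — multi-state microsimulation, risk-score eligibility,
lipid-mediated treatment effects, discounted QALY/cost accumulation, and
probabilistic/deterministic sensitivity analysis.

## The model

Individuals enter CVD-free and move through annual cycles over the state
space

```
CVD-free ──► non-fatal CHD ──► death after event
    │  └───► non-fatal CBVD ─► death after event
    ├──────► fatal CVD death
    └──────► non-CVD death
```

* **First events.** Four competing cause-specific Gompertz hazards
  `h_k(t) = exp(β_k·x) · exp(γ_k t)` with the ASSIGN risk factors as
  covariates (age, sex, systolic BP, total and HDL cholesterol,
  cigarettes/day, diabetes, family history, area deprivation/SIMD). A cycle
  is split exactly under within-cycle proportionality:
  `p_k = (H_k/H)(1 − e^{−H})`, `stay = e^{−H}`.
* **After a non-fatal event.** An all-cause Gompertz model (age at event,
  SIMD, family history; timescale = years since event) governs death, and a
  probit model `Φ(β·x)` gives the per-cycle probability of recurrent events,
  which carry extra costs and utility decrements.
* **Eligibility.** The ASSIGN 10-year risk,
  `risk = 100·(1 − S₀^{exp(LP − L̄P)})`, with treatment offered at
  `risk ≥ 20%` or `≥ 10%`.
* **Treatment effect.** A strategy removes a percentage of each individual's
  non-HDL cholesterol (TC − HDL); relative risks per 1.0 mmol/L reduction
  (0.77 non-fatal CHD, 0.87 non-fatal CBVD, 0.90 fatal CVD) scale the
  first-event hazards as `RR^Δ`. Side effects enter as an expected annual
  diabetes-treatment cost (absolute risk increase × £314.33/yr; negative for
  berberine) and a pill-taking disutility (0.002 QALY/yr).
* **Economics.** Life-years undiscounted; QALYs and costs discounted at
  3.5%/yr over a lifetime horizon (to age 110). ICER = ΔC/ΔQ against either
  no intervention or the statin strategy; NNT = treated per first CVD event
  prevented; willingness-to-pay threshold £20,000/QALY. PSA re-draws every
  uncertain parameter from beta/gamma/log-normal distributions fitted to the
  base case and 95% CI; CEACs report the probability each strategy maximises
  net monetary benefit. One-way DSA produces tornado tables.

Because the survey microdata and the published regression tables are not
redistributable, the package ships a **synthetic cohort generator** with the
reported structure of the eligible population (55.6% women; women with lower
SBP, higher TC, higher HDL-c) and **placeholder regression coefficients**
(flagged `provenance: placeholder`, with a loud warning) calibrated to
realistic Scottish event rates and eligibility fractions (~34% at the 20%
threshold, ~60% at 10%). Absolute levels are therefore illustrative; the
incremental *pattern* is the reproducible object.

## Worked example

```python
from cvdcea import CvdPolicyModel

model = CvdPolicyModel.from_config(region="scotland", n=500, seed=11)
res = model.fit()                      # reference: no intervention
print(res.summary())
```

```
Cost-effectiveness of primary CVD prevention strategies
========================================================================
Cohort size:        500
Eligibility:        10-year risk >= 20% (155 treated)
Reference strategy: No intervention
Price region:       Scotland   discount 3.5%/yr   WTP 20,000/QALY
NOTE: placeholder regression coefficients — absolute levels are illustrative.
------------------------------------------------------------------------
               strategy       reference  ...  qalys_gained  incremental_cost   icer
                Statins No intervention  ...          24.0           55723.3 2317.1
              Berberine No intervention  ...          18.9          142351.4 7534.5
Combined intervention 1 No intervention  ...          44.9          205459.2 4575.0
Combined intervention 2 No intervention  ...          48.7          128737.6 2643.5
```

Of 500 synthetic adults, 155 have 10-year risk ≥ 20%. Treating them with a
statin prevents ≈ 8.1 first CVD events (NNT 19.1), gains 24.0 discounted
QALYs for £55,723 extra — £2,317 per QALY, comfortably cost-effective at
£20,000/QALY. All four active strategies are cost-effective against no
intervention; switching the reference (`model.fit(reference="Statins")`)
shows berberine *dominated* by statins at Scottish prices (dearer and less
effective), while both combinations remain cost-effective. With the bundled
China price configuration (`region="china"`, berberine cheaper than statins)
berberine is no longer dominated.

Sensitivity analysis hangs off the same objects:

```python
psa = model.run_psa(n_iter=1000, seed=1)   # parameter-level Monte Carlo
psa.ceac()                                  # P(optimal) across WTP grid
psa.plot_ceac("ceac.png")
model.tornado(strategy="Statins")           # one-way DSA table
```

The same pipeline is scriptable from a shell:

```bash
cvdcea synth --n 3869 --seed 1 --out cohort.csv
cvdcea cea  --cohort cohort.csv --threshold 20 --out results/
cvdcea psa  --cohort cohort.csv --iterations 1000 --seed 1 --out results/
cvdcea dsa  --cohort cohort.csv --strategy Statins --out results/
```

Every run writes a `manifest.json` with the config hash, seed, coefficient
provenance, and the cohort's eligible fractions.

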