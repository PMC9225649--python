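# crswnp-cea

A cost–utility model of **dupilumab added to best supportive care (BSC)
versus BSC alone** in adults with severe, uncontrolled chronic rhinosinusitis
with nasal polyps (CRSwNP), from the Italian National Healthcare Service
(NHS) or societal perspective.

The package is aimed at health-economics analysts who want a transparent,
tested, scriptable implementation of this class of model: a 1-year decision
tree feeding a lifetime Markov cohort model, valued as discounted
quality-adjusted life years (QALYs) and costs, with deterministic and
probabilistic sensitivity analysis.

## The model

**Year 1 — decision tree.** All patients start on their assigned strategy.
Response (SNOT-22 improvement ≥ 8.9 points *and* nasal polyp score
improvement ≥ 1 point) is assessed at week 24; week-24 responders are
re-assessed at week 52, giving three terminal branches per arm with
probabilities

```
P(NR24) = 1 − p24        P(NR52) = p24 (1 − p52|24)        P(R52) = p24 p52|24
```

Year-1 QALYs time-weight the baseline (weeks 0–12), treatment-specific
(weeks 12–24) and response-status (weeks 24–52) utilities; year-1 costs
combine half-year therapy/medical costs by response status, drug
acquisition (week-24 non-responders stop after 24/52 of the annual
administrations), and adverse events.

**Years 2+ — Markov cohort.** Week-52 responders enter *Controlled disease*;
non-responders enter *Inadequately controlled disease*, 15.1% of them
permanently ineligible for surgery. Annual transitions: controlled patients
discontinue with probability 0.02 (98% sustained response); eligible
uncontrolled patients (pre- or post-operative) undergo surgery at 1.9%/year
while under age 70; *Surgery* is a one-cycle tunnel to *Post-operative
controlled*, from which 40%/year relapse to *Post-operative uncontrolled*.
Background mortality from a life table applies first in every cycle,
identically across alive states.

**Valuation.** With cohort occupancy `x_k` at cycle `k`, utilities `u`, and
annual rate `r = 3%`,

```
QALYs = QALY_tree + Σ_k (1+r)^−k · xₖᵀu          Cost = Cost_tree + Σ_k (1+r)^−k · cₖ
ICUR  = (C_int − C_comp) / (Q_int − Q_comp)
```

with costs grouped as drug acquisition, disease management (state costs +
surgical episodes + post-operative follow-up), adverse events, and — under
the societal perspective — productivity losses (workdays lost × 8 h ×
€29.80/h). Sensitivity analysis: one-way ±10% tornado; probabilistic
analysis with moment-matched Gamma (costs), Beta (probabilities/incidence
rates) and [0,1]-truncated Normal (utilities) distributions; acceptability
curve `CEAC(λ) = P(λ·ΔQ − ΔC ≥ 0)`.

**Placeholders.** Four inputs of the original evaluation are not public: the
arm-specific response probabilities (published only as a figure), the net
per-administration drug price, the mortality schedule, and per-state
workdays lost. The packaged fixture substitutes clearly flagged
placeholders (see `fixtures/provenance.txt`), and every report carries a
watermark listing them — so numbers produced from the defaults are
*illustrative*, not the published results. Supply your own values in a
config file to analyse a real pricing scenario.

## Worked example

```python
from crswnp_cea import CostUtilityModel

model = CostUtilityModel.default()     # packaged fixture (placeholders flagged)
results = model.fit()
print(results.summary())
```

prints

```
========================================================================
      Cost-utility analysis: dupilumab + BSC vs BSC alone (CRSwNP)
========================================================================
                                         dupilumab+BSC         BSC
------------------------------------------------------------------------
QALYs (discounted)                               17.09       16.31
Life years (discounted)                          20.53       20.53
Drug acquisition costs (EUR)                   132,346           0
Disease management costs (EUR)*                271,169     313,029
Adverse events costs (EUR)                         723       1,370
TOTAL costs (EUR)                              404,237     314,399
------------------------------------------------------------------------
Incremental cost (EUR):  89,838
Incremental QALYs:       0.77
ICUR (EUR/QALY):         116,132
* disease management includes surgical episodes and follow-up
------------------------------------------------------------------------
WATERMARK - placeholder inputs in use (results are illustrative,
not the published evaluation):
  [synthetic] drug.price_per_administration
  ...
========================================================================
```

Reading the output: both arms live the same expected 20.53 discounted life
years (the model has no disease-specific mortality), but the dupilumab arm
spends far more of that time in the controlled state, gaining 0.77 QALYs.
At the placeholder list-price of €580 per administration the lifetime drug
cost is €132,346 and the incremental cost-utility ratio is €116,132 per
QALY — the watermark block is the reminder that this reflects the
placeholder price and response rates, not the confidential Italian net
price. Disease-management savings (−€41,860) and adverse-event savings
partially offset the drug cost.

Sensitivity analysis and scenarios from the same objects:

```python
entries = model.owsa()                     # tornado, sorted by ICUR span
draws   = model.psa(n=1000, seed=42)       # (ΔC, ΔQ) cloud, reproducible
societal = model.scenario("societal").fit()
lower_compliance = model.scenario("compliance", rate=0.9695).fit()
```

Or from the shell:

```bash
crswnp-cea run  --out out/                       # traces + summary JSON/CSV
crswnp-cea owsa --out out/                       # tornado.csv
crswnp-cea psa  --n 1000 --seed 42 --out out/    # ce_plane.csv + ceac.csv
crswnp-cea scenario --name compliance --rate 0.9695 --out out/
crswnp-cea fixtures --out fixtures/              # regenerate the input bundle
```

Configuration files are YAML validated against
`src/crswnp_cea/schema/config.schema.json`; any subset of keys may be given
and the rest are filled from the packaged defaults. The published lifetime
discounted drug cost (€76,383) can be used to back-solve a net price under
your own assumptions — the package deliberately never does this silently.

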