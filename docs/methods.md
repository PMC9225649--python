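# Methods

This note documents the model implemented in `crswnp_cea`: its structure and
assumptions, the parameters that matter, what the synthetic inputs emulate,
the numerical conventions, and the design choices made where the structure
was genuinely open.

## Model structure

The analysis compares two strategies in adults with severe uncontrolled
CRSwNP: dupilumab 300 mg every two weeks added to best supportive care
(intranasal/oral corticosteroids, saline irrigation, possible surgery)
versus best supportive care alone.

**Decision tree (year 1).** Response is assessed at week 24 and, for
week-24 responders, again at week 52. Response probabilities are stored as
the week-24 marginal and the week-52 *conditional-on-week-24-response*
probability, because only week-24 responders are re-assessed; a helper
(`ResponseProbabilities.conditional_from_marginal`) converts from marginal
week-52 rates. Branch QALYs partition the 52-week year as 12 weeks at
baseline utility (0.769), 12 weeks at the treatment-specific utility (0.875
dupilumab / 0.810 BSC — the only treatment-dependent utilities in the
model), and 28 weeks at the assessed-status utility (0.891 responder /
0.808 non-responder).

**Markov model (years 2+).** Seven states: Controlled, Inadequately
controlled (split into surgery-eligible and -ineligible substates),
Surgery (a one-cycle tunnel), Post-operative controlled, Post-operative
uncontrolled, Death. Annual cycles; the cohort's fractional start age
(51.39) advances exactly one year per cycle, and life-table lookups floor
the age to whole years, matching the annual transition probabilities.

## Parameters

| Parameter | Default | Unit | Role |
|---|---|---|---|
| start age | 51.39 | years | cohort entry age |
| sustained response | 0.98 | /year | probability a controlled patient keeps responding |
| surgery-ineligible share | 0.151 | proportion | persistent attribute of the uncontrolled population |
| annual surgery probability | 0.019 | /year | eligible uncontrolled patients, under age 70 only |
| post-operative relapse | 0.40 | /year | Post-op controlled → uncontrolled |
| state utilities | 0.913 / 0.776 / 0.820 / 0.827 / 0.760 | — | controlled / inadequate / surgery / post-op controlled / post-op uncontrolled |
| state management costs | 8,937 / 16,536 | EUR/year | controlled-like / uncontrolled-like states (US estimates converted at PPP 0.648) |
| surgical episode | 104 + 2,009 | EUR | CT work-up + day-hospital procedure, per surgery entry |
| post-op follow-up | 103 | EUR/year | 5 specialist visits × €20.66, rounded to whole euros |
| adverse events | 35.21 / 66.76 | EUR/year | rate-weighted unit costs, dupilumab / BSC arm |
| discount rate | 0.03 | /year | costs and effects alike |
| horizon | age 110 | years | effective lifetime horizon |

The eligibility split (84.9% / 15.1%) is re-applied whenever mass newly
enters the inadequately-controlled compartment, including patients
discontinuing from Controlled — they may later undergo (repeat) surgery,
and post-operative patients keep eligibility until 70. Two rows of the
published transition table carry the same transition label with values 1.9%
and 98.1%; the 98.1% is treated as the complementary stay-probability.

## Synthetic inputs and what they (do not) show

Four inputs are not public and are generated by `crswnp_cea.synthetic`:

- **Response probabilities** — placeholders (dupilumab 0.60 / 0.90, BSC
  0.25 / 0.70 in the marginal/conditional convention), tagged
  `figure-only-placeholder`. Chosen once as mid-range plausible values for
  an effective biologic versus background therapy; they are *not* the trial
  estimates.
- **Mortality** — a Gompertz–Makeham schedule `q(age) = 1 − exp(−(a + b
  e^{c·age}))` with `a = 5·10⁻⁴`, `b = 2·10⁻⁵`, `c = 0.095` per year,
  chosen to give a life expectancy at birth of ≈ 81.8 years (Italy-like),
  deterministic and seedless. Users can substitute a national life table as
  a CSV (`age,qx`).
- **Drug price** — €580 per administration, the order of magnitude of
  published Italian ex-factory biologic prices; the confidential net price
  is lower. The config schema treats the price as *required*: the packaged
  fixture is the only place a default exists, and it is tagged `synthetic`.
- **Workdays lost** — 4.8 days/year in uncontrolled-like states (a
  published survey average for chronic rhinosinusitis), 0.5–1.0 in
  controlled-like states; societal-perspective results therefore indicate
  direction and mechanics, not magnitude.

Because of these placeholders, passing tests demonstrate that the *engine*
is correct (conservation, closed forms, agreement with an independent
microsimulation, correct discounting and incremental arithmetic), not that
the packaged numbers reproduce the published evaluation — which is
impossible without the confidential inputs. Provenance tags are mandatory
for every numeric parameter, and reports watermark all placeholder-derived
output.

## Numerical and structural conventions

- **Competing risks.** Death is applied first each cycle; clinical
  transitions act on survivors. Mortality is state-independent (no
  disease-specific excess mortality), which makes the cohort's alive mass
  exactly the life-table survival product — asserted in the tests.
- **Discounting.** Year 1 is time 0 (undiscounted); Markov cycle k is
  discounted by (1+r)^−k for both costs and effects.
- **Half-cycle correction** is off by default (annual probabilities, no
  stated correction) and available as a switch, valuing cycle k at the mean
  of its start- and end-of-cycle occupancy.
- **Week-52 non-responders** accrue responder *utility* over weeks 24–52
  (they respond until the week-52 assessment) but non-responder *costs*
  (cost rows key on eventual response status). Switchable
  (`switches.nr52_responder_utility`).
- **Within-year surgery**: tree non-responders move to inadequately
  controlled at year end; surgical transitions start in Markov year 2 at
  the 1.9% annual rate, the only quantified surgical pathway.
- **Tree mortality** is off by default (trial-like year 1); a switch
  applies one year of background mortality at the year boundary.
- **Adverse-event costs** accrue over the whole alive lifetime at
  arm-specific rates (switchable to year-1-only), mirroring lifetime
  arm-specific AE cost reporting.
- **Post-operative follow-up** (€103/year) is added on top of the post-op
  state management cost; the composition of the US-derived state costs is
  not published, so this is an explicit switch
  (`switches.postop_followup_separate`).
- **Currency** is stored at two decimals on load; arithmetic runs in full
  float64 precision; rounding to whole euros / 2-decimal QALYs happens only
  in rendered reports (JSON keeps full precision).
- **Horizon.** The run stops when the cohort age exceeds 110 or the alive
  mass falls below 10⁻⁹; with the default start age this is 58 Markov
  cycles. Residual occupancy past the horizon is truncated, as usual for
  lifetime cohort models.
- **ICUR quadrants.** Dominance (cheaper-and-better, or
  costlier-and-worse) suppresses the ratio; the southwest quadrant keeps
  the ratio but is always labelled, never reported bare. Tornado entries
  record the raw ratio in every quadrant (flagged with the dominance
  status) so spans stay defined.

## Sensitivity analysis

- **OWSA**: every substantive probability, utility, cost and AE rate plus
  the structural settings (discount rates, surgical age cutoff) varied
  ±10% (no 95% CIs are published); probabilities clamped to [0,1]; the
  base configuration is restored between runs.
- **PSA** (structural settings excluded): Gamma for costs with shape
  `(m/se)²`, scale `se²/m`; Beta by method of moments `α = m·ν`,
  `β = (1−m)·ν`, `ν = m(1−m)/se² − 1`; utilities from a Normal truncated to
  [0,1]. Default `se = 0.1·m` (mirroring the ±10% OWSA rule); degenerate
  means (0 or 1) are held fixed. Truncation at utilities near 1 shifts the
  realised mean visibly, so moment-recovery checks compare against the
  truncated distribution's analytic moments. A single `numpy` Generator
  seeded from the run seed drives all sampling; the same seed reproduces
  the draws bit for bit.
- **WTP grid**: €0–100,000 in €500 steps, containing the informal Italian
  acceptability endpoints (€25,000; €40,000) and midpoint (€32,500).
- **Scenarios**: societal perspective (adds the indirect component and
  changes nothing else) and reduced compliance 96.95% (scales drug
  acquisition only; efficacy untouched, so QALYs are invariant by
  construction).

## Verification

The test suite checks, among others: trace rows sum to 1 within 10⁻¹²
with monotone death occupancy; a seeded 200,000-individual microsimulation
that independently re-implements the transition rules matches every trace
cell within 4 binomial standard errors; closed forms (0.98^k controlled
decay, survival products, geometric discounted-QALY series); PSA
moment-matching against hand-worked algebra and 10,000-draw moment
recovery; acceptability-curve endpoints at λ = 0 and λ → ∞; and exact
arithmetic identities among the published results-table values.
`scripts/acceptance.py` re-runs the full pipeline (base case, scenarios,
tornado, 1000-draw PSA) from scratch at a chosen seed.

## Known limitations

- No sex-stratified or disease-specific mortality; the reported 60.4% male
  share is carried but unused.
- No treatment waning beyond the 2%/year discontinuation, no dupilumab
  re-treatment after discontinuation, no cap on post-operative persistence.
- Independent parameter sampling in the PSA (no correlation structure).
- No cost inflation engine (tariffs consumed as already indexed).
- Placeholder-driven defaults: absolute results from the packaged fixture
  are illustrative until users supply the confidential price and the trial
  response rates.
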