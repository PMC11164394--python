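# Methods

## Model overview

`gcsf_cea` implements a two-phase Markov cohort model of granulocyte
colony-stimulating factor (G-CSF) prophylaxis against chemotherapy-induced
febrile neutropenia (FN) in women with early breast cancer, from a national
single-payer perspective with costs in 2022 New Taiwan Dollars (NTD).  A
hypothetical cohort of 56-year-old women receives six 21-day cycles of a
high-FN-risk regimen and is then followed in annual cycles until the whole
cohort is dead (terminal age 110).  Seven strategies are compared in the
base case: no prophylaxis, and secondary (SP) or primary (PP) prophylaxis
with filgrastim, lenograstim, or pegfilgrastim; a scenario adds the
filgrastim and pegfilgrastim biosimilars, which differ from their reference
products only in unit price.

### Chemotherapy phase

Each cycle, an alive patient either has one FN event or none.  The FN
probability is multiplicative:

    p = p1 x r2 [cycle >= 2] x rh [FN history] x rd [on G-CSF],  capped at 1

with first-cycle baseline risk `p1 = 0.364`, later-cycle relative risk
`r2 = 0.46`, history relative risk `rh = 2.4`, and drug relative risk `rd`
tiered by chemotherapy cycle number (cycles 1–2 vs 3+ for the short-acting
drugs; one value, 0.334, for pegfilgrastim).  An FN event is fatal with
probability 0.036; FN survivors carry history permanently.  Primary
prophylaxis treats every cycle from cycle 1; secondary prophylaxis starts
the cycle after the first FN event and continues in all remaining cycles.

Timing conventions (these reconcile the published per-strategy cost totals,
which all reproduce to within NT$0.5):

* FN and FN death resolve at cycle end.  A patient dying in cycle *k*
  accrues that cycle's drug cost, the FN event cost, and the cycle's
  chemotherapy QALY minus the FN hospitalisation decrement, then nothing.
* Drug cost accrues for every patient alive at cycle start who is eligible
  under the strategy: 4 injections/cycle for the short-acting drugs, 1 for
  pegfilgrastim, at the NHI reimbursement price per injection.
* Fatal FN events incur the full NT$8,287 event cost.
* QALYs: utility 0.78/year for 21 days per cycle, minus a 0.36/year
  decrement over the 10.53-day FN hospitalisation per event.  Chemotherapy
  QALYs are not discounted (the phase ends within year 1).  Year length is
  365.25 days.

The phase is evaluated as an exact expectation over the three-state
(no-history / history / dead) chain, which the test suite checks against a
brute-force enumeration of every event path (agreement to 1e-10) and
against a 10^6-patient microsimulation (agreement within 3 SEs).

### Post-chemotherapy phase

At the end of chemotherapy, survivors split by FN history and then by
relative dose intensity (RDI): P(RDI < 85%) is 0.247 without history, and
0.247 x RR with history, where the published odds ratio 1.58 is converted
to a risk ratio via RR = OR / (1 - p + p·OR) at baseline p = 0.247
(giving 1.382).

Annual mortality is 2.02% for post-chemotherapy years 1–10 (breast-cancer
mortality derived from 10-year survival), then the general-population
female life-table rate at the attained age.  The 2.02% is treated as the
RDI >= 85% baseline; the RDI < 85% stratum applies the mortality hazard
ratio 1.73 on the hazard scale, `q' = 1 - (1-q)^HR`, which stays within
[0, 1] even at the sensitivity-range extremes where naive multiplication
would not.  Scenario 1 severs this link entirely (both strata face
baseline mortality).

QALYs use survivor utilities 0.84/year (post-chemo years 1–5) and
0.91/year (after year 5), discounted at 3%/year with the discount clock
starting at the end of chemotherapy; person-years are half-cycle corrected
(mean of start/end-of-year survivors).  Costs are never discounted — all
costs fall in the chemotherapy phase.  Age advances with the post-chemo
year; the ~18-week chemotherapy duration is ignored for age indexing.

### Frontier, dominance, ICERs

Strategies are ordered by total cost.  A strategy is strongly dominated if
another costs no more and yields no fewer QALYs (one inequality strict);
exact ties in both are kept, ordered by label.  Extended dominance then
iteratively removes members whose segment ICER is not strictly below the
next segment's, leaving a strictly increasing ICER sequence.  Property
tests check the frontier against a brute-force net-monetary-benefit
maximiser over a slope-refined willingness-to-pay grid.  All comparisons
use unrounded values; rounding (integer NT$, 2-decimal QALYs) happens only
in writers.

## Sensitivity analyses

* **One-way (tornado):** the ICER of a comparison is recomputed at each
  parameter's range endpoints.  Ranges are 95% CIs or published plausible
  bands; FN event cost uses ±20%; G-CSF prices use −20% to 0% (reimbursement
  prices only adjust downwards).  No published range exists for the
  discount rate, which the published tornado nevertheless ranks among the
  top four levers; this package uses the conventional 0–5% band.
* **Threshold search:** Brent root-finding on the ICER-minus-target
  function over a user-supplied bracket, to within NT$1/QALY.  The ICER is
  only piecewise monotone — it has a singularity where the incremental
  QALYs cross zero (for the pegfilgrastim-vs-lenograstim comparison this
  happens near RR ≈ 0.52) — so the bracket must stay within the monotone
  region; the search raises a no-crossing error otherwise.
* **PSA:** 10,000 second-order Monte Carlo draws, parameters independent
  (no correlation structure is published).  Beta and gamma distributions
  are fitted by method of moments with SE = (high − low)/3.92; log-normal
  with meanlog = ln(base), sdlog = (ln high − ln low)/3.92.  Drug prices
  and the discount rate stay fixed.  Biosimilar effectiveness follows the
  redrawn reference-product RR.  Per draw, all strategies are evaluated
  and the net-monetary-benefit maximiser recorded over a WTP grid
  (default 0 to 1.5x the NT$976,914 threshold in NT$10,000 steps),
  yielding cost-effectiveness acceptability curves.  The distribution-fit
  method from mean + range is this package's declared choice; the source
  analysis does not state one.

## Synthetic inputs

Two inputs cannot ship with the package and are emulated:

* **Life table.**  The packaged table is a Gompertz schedule
  `qx = min(1, a·e^{0.095(x−56)})` on ages 56–110, with `a` calibrated by
  root finding so residual life expectancy at 56 is 29.0 years
  (approximating a Taiwanese woman of that age); `qx(110) = 1`.  With this
  stand-in the model reproduces the published dominance pattern, QALY
  ordering, and frontier ICERs to within a few percent (60,005 and 254,259
  NT$/QALY vs the published 61,995 and 269,683); exact ICER reproduction
  requires the actual Ministry of the Interior table, which can be dropped
  in through the same two-column CSV interface.
* **Claims-like cohort records.**  `simulate_cohort` draws per-patient,
  per-cycle Bernoulli FN events from the same risk model the engine uses,
  with secondary-prophylaxis triggering and FN-death truncation.  Claims
  exclusion filters are represented only as a uniform record-drop
  fraction; their selective structure is not reconstructible.  The
  generator emulates the risk structure, not claims-format realism, so
  passing recovery tests show estimator correctness under the model's
  assumptions — not robustness to real-world coding error or confounding
  beyond FN history.

### Relative-risk re-estimation

`estimate_rr` compares FN incidence in drug-exposed vs unexposed cycles
within a cycle tier (1–2 or 3+) using a Mantel–Haenszel ratio of incidence
proportions stratified by (cycle, FN history).  The crude ratio is
confounded: exposure correlates with FN history through the
secondary-prophylaxis trigger and differential attrition (numerically, the
crude cycles-1–2 lenograstim RR is ~0.37 against a true 0.452), while the
stratified estimator is unbiased because the generator's risk model is
multiplicative within strata.

The CI uses a patient-clustered linearisation variance rather than the
classical independent-strata (Greenland–Robins) form: a patient's early FN
outcome both contributes an event and reassigns their later history
strata, so stratum counts are cross-correlated and the classical variance
measurably undercovers (~93–94% at nominal 95% on these records).
Influence contributions are summed per patient, centred within the
ever-exposed / never-exposed patient groups (patients with no record in a
stratum count as zeros), giving measured coverage of 95–98% with bias
~0.001 across all five drug-RR parameters.

## Problem sizes and numerical choices

* Recovery studies use ~17,000 patients per replicate (~100,000 cycle
  records) and 100 replicates per parameter; microsimulation cross-checks
  use 10^6 patients.
* Root finding uses `scipy.optimize.brentq` with xtol 1e-12 (threshold
  search) and 1e-14 (life-table calibration).
* Cohort-mass conservation is asserted to 1e-12 every chemo run.
* The FN probability cap at 1 never binds at base case; it matters only at
  one-way-sensitivity extremes.
* Random draws use `numpy.random.default_rng`; all stochastic entry points
  take explicit seeds and are reproducible bit-for-bit.

## Known limitations

* No breast-cancer recurrence/progression states, no chemotherapy drug or
  administration costs, no antibiotic prophylaxis, and RDI is a binary
  split — all by design of the source model.
* Whether the 2.02% annual mortality applies to the whole cohort or the
  RDI >= 85% stratum is not stated in the source; this package treats it
  as the baseline stratum rate (consistent with the higher QALYs observed
  when the RDI effect is removed) and exposes Scenario 1 as the
  alternative.
* Post-chemo "years 1–5" utility is indexed from the end of chemotherapy,
  not diagnosis.
* The published ICERs and PSA probabilities are reproduced only
  approximately under the synthetic life table; the qualitative results
  (dominance pattern, CEAC shape, tornado ranking) are insensitive to
  that substitution.
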