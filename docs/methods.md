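# Methods

## Model structure

The model is a discrete-time Markov cohort simulation of one eye (the
better-seeing eye; a monocular simplification) of a 50-year-old patient with
proliferative diabetic retinopathy, run in 1-year cycles until age 100.
Clinical states: NPDR (regressed disease under follow-up), PDR (active
neovascularisation), DME (macular oedema, treated with anti-VEGF), SVL
(severe visual loss, VA < 0.1, absorbing except for death) and DEAD.

Because several quantities depend on history, the clinical states are
expanded with attributes: the therapy line that applies to the next PDR
episode (`first`/`second`, for the two sequential strategies), the last PDR
therapy administered (recurrence from NPDR is 1.15× higher after anti-VEGF
than after PRP), a permanent "ever received PRP" flag (peripheral
visual-field-defect disutility of 0.01 from the first PRP onward), the state
a DME episode arose from (successful DME treatment returns the patient
there), and the SVL tenure year 1–5+ as tunnel states (the probability of
continuing twice-yearly injections declines with tenure: 0.914, 0.736,
0.65, 0.609, 0.537, then 0.481).  The state space is the breadth-first
reachability closure per strategy (13–25 states plus DEAD).

### Within-cycle ordering

1. **Death** first: the life-table probability times the diabetes mortality
   ratio 1.49, times 11.54 in SVL, capped at 1.
2. **PDR occupants** (survivors): 20% miss treatment that cycle (loss to
   follow-up, redrawn each cycle); the treated 80% receive the current
   line's therapy.  Success (PRP 0.2008; anti-VEGF 0.2008×1.75) moves the
   patient to NPDR.  Failed-or-untreated occupants face the SVL (0.18) and
   DME (0.179) hazards.  A *failed treated* cycle switches a two-line
   strategy to its second line for all subsequent cycles.
3. **NPDR occupants**: recurrence to PDR (0.0169 after PRP, ×1.15 after
   anti-VEGF) or DME (0.1522).
4. **DME occupants**: resolve with 0.534 back to their origin state.
5. **Endophthalmitis** after injections is folded in as a per-injection
   probability 0.0006×(1−0.595) of transition to SVL plus an expected
   treatment cost, rather than as an explicit state — the cohort's
   occupancy of an endophthalmitis state is never itself of interest.

Rewards accrue on the state occupied at the start of the cycle; cycle *t*
is discounted by (1.045)^−t with the first cycle undiscounted, and no
half-cycle correction is applied (the convention is recorded in the result
metadata and the exponent can be shifted via `SimulationSettings` for
sensitivity checks; shifting scales results by exactly 1/1.045).  Costs and
effects share the single 4.5% rate.

### Treatment dosing and costs

PRP bills one episode per treated PDR-year.  Anti-VEGF bills three
injections per treated year in PDR and DME (the loading-dose schedule
generalised to the annual cycle) and two per year in SVL, scaled by the
tenure-year continuation probability.  Care cost ($11,826/yr) accrues in
SVL only while age < 90, a deliberate cap against overestimating care that
would be needed in extreme old age regardless of blindness; low-vision
glasses ($27/yr) are counted as non-covered medical cost.

**Reimbursement.** Anti-VEGF injection is not covered by the national
insurer for PDR (only PRP is), so injections billed for PDR treatment are
classified wholly as non-covered medical cost and are invisible to the
payer perspective.  Injections for DME and the SVL continuation injections
— both observed in insurer claims — keep the published covered/non-covered
split ($447/$63 per episode).  This classification is what makes all three
anti-VEGF-containing strategies cost-saving from the payer perspective, as
in the source analysis; billing PDR injections as covered would reverse it.

### Utilities

The published per-state utilities are age ranges with a common span of
0.055 (e.g. NPDR 0.849–0.904).  They are parameterised as the age-50
anchor, declining linearly to the lower value at age 100.  Anchors above 1
(possible under sensitivity analysis) are censored to 1; the pVFD
disutility is subtracted afterwards and the result floored at 0.

## Mortality

The default life table is a Gompertz schedule q(x) = 1 − exp(−a·e^{bx})
with a = 2.8×10⁻⁵, b = 0.09 — a stand-in calibrated to plausible East-Asian
adult mortality (q(50) ≈ 0.0025, q(80) ≈ 0.036, q(100) ≈ 0.20).  The
national table used in the source analysis is not published; any `age,q`
CSV can be substituted, and every mortality-dependent output is approximate
by construction.  Relative risks act multiplicatively on the annual
probability (not the rate) and are capped at 1; the SVL ratio multiplies
the already diabetes-adjusted probability.

## Sensitivity analysis

**One-way (tornado).** Each ranged parameter is set to its bounds — the
published ±20% range, the 95% CI for the three relative risks with one, or
the printed explicit ranges (discount 3–7%, pVFD disutility 0.005–0.02) —
holding everything else at base, and the pairwise ICER is recomputed.  The
SVL mortality ratio (11.54) has no published interval and is held fixed
everywhere.  Utility bounds above 1 are censored to 1 before evaluation.

**Probabilistic.** Families follow the published table: beta for most
probabilities, symmetric triangle for the PDR→SVL probability, loss to
follow-up and the utility anchors, gamma for every cost component,
lognormal for relative risks, fixed for the continuation vector and
discount rate.  The ±20% range is interpreted as a 95% interval, giving
SE = 0.2·base/1.96 for method-of-moments beta/gamma; lognormal uses
μ = ln(base) and σ = (ln hi − ln lo)/(2·1.96).  Draws are independent
across parameters (no correlation structure is published).  Out-of-domain
draws are rejected and redrawn — preserving the stated family — except
utilities, which are censored at 1 per the published rule.  The CEAC uses
maximal net monetary benefit as the optimality rule, with exact ties split
equally; the default WTP grid is $0–100,000/QALY in $1,000 steps, covering
the published $24,400 threshold.

Note that the PSA mean is not the base case: censoring the utility draws at
1 shifts their mean ~0.3% below the anchor, and the lognormal relative
risks have mean base·exp(σ²/2) with concave downstream effects.  Together
these displace mean PSA QALYs ~0.5% below the base case — visible, expected,
and covered by the 1% band in the consistency test.

## Validation

* An individual-level microsimulation (`microsim_oracle`) pushes n
  simulated patients through the identical transition probabilities and
  accounting; at n = 50,000 it agrees with the cohort engine within 3
  Monte-Carlo SEs on costs and QALYs for every strategy.
* Transition matrices are row-stochastic to 10⁻¹² and the cohort trace
  conserves mass to 10⁻¹⁰ across 1,000 random parameter draws.
* The efficiency frontier matches an O(n³) brute-force dominance oracle on
  1,000 random instances.
* The synthetic macro-costing and utility-survey estimators recover their
  generating values (within 5% at 10,000 patient-years; within 3 SE at 300
  respondents per state).

## Synthetic data

The original inputs (insurer claims for costs, a 300-patient EQ-5D survey
for utilities, the national life table) are not distributable.  The
`synthetic` module emulates their *structure*: per-patient-year episode
records with independent gamma cost components (CV 0.8 by default — a
stand-in; real claims dispersion is unknown) and beta-distributed utility
responses (SD 0.08).  Passing recovery tests therefore demonstrates that
the estimators are correct on data of that form, not that the published
point estimates are right; the model's parameters remain the published
values, not re-estimated ones.

## Design choices on genuinely open points

* DME resolution returns to the originating state (the source does not say
  where successful DME treatment leads).
* The SVL/DME hazards apply to PDR occupants *not cured that cycle*;
  applying them to the newly cured as well would double-count cure.
* Line switching happens after a single failed treated cycle ("if the
  treatment does not work"); untreated cycles do not switch.  The
  alternative reading — both therapies within one cycle, the second on
  failure of the first — was evaluated and rejected because it makes the
  sequential strategies more effective than anti-VEGF-only, contradicting
  the source's effectiveness ordering.
* No direct NPDR→SVL or DME→SVL disease transitions (absent from the
  published transition diagram); endophthalmitis provides the only
  DME→SVL route.

## Reproduction status and known limitations

With base parameters and the default life table the package reproduces the
published *qualitative* pattern: positive healthcare-perspective ICERs with
PRP-first the least favourable; all three anti-VEGF-containing strategies
cost-saving from the payer and societal perspectives with anti-VEGF-only
least costly and most effective; acceptability curves in which PRP-only
leads at low willingness-to-pay from the healthcare perspective with a
finite crossing to anti-VEGF-only, and anti-VEGF-only leading at every WTP
from the payer and societal perspectives.

Absolute values differ (QALYs ~11.3–12.4 vs the published 13.07–13.26;
healthcare ICERs ~$2,700–3,100/QALY vs $33,405–95,456), as expected: the
national life table, TreeAge cycle conventions and several dosing details
are not published, and the model accrues substantially more SVL mortality
than the source appears to.  One fine-grained ordering does not reproduce:
anti-VEGF-first's healthcare ICER lands ~1% *below* anti-VEGF-only's
(2,689 vs 2,718 $/QALY) where the source places it ~3% above (34,375 vs
33,405) — a knife-edge property of whether the mixed strategy sits above or
below the PRP-only↔anti-VEGF-only cost-effectiveness chord, which the
unpublished conventions decide.  The corresponding acceptance test asserts
the source's full ordering and is expected to fail on that single
comparison.

Problem sizes used by the test suite and acceptance script (50-cycle
cohort, 2,000 PSA draws, 50,000 microsimulated individuals, 10,000
synthetic patient-years, 300 survey respondents per state) are the
package's own defaults for routine verification; release-quality PSA
figures use 10,000 draws via `pdrcea psa --n 10000`.
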