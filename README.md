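# pdrcea

A Markov cohort cost-effectiveness model comparing treatment strategies for
**proliferative diabetic retinopathy (PDR)**: panretinal photocoagulation
(PRP), anti-VEGF intravitreal injection, and the two sequential policies
(PRP first, anti-VEGF first).  The package is aimed at health-economics and
HTA analysts who want a fully scripted, testable counterpart to the usual
spreadsheet/TreeAge workflow: deterministic cohort simulation, incremental
cost-effectiveness from three perspectives, tornado-style one-way sensitivity
analysis, and probabilistic sensitivity analysis with cost-effectiveness
acceptability curves.

## The model

A hypothetical cohort of 50-year-old PDR patients is followed in annual
cycles to age 100 through five clinical states — NPDR, PDR, DME (diabetic
macular oedema), SVL (severe visual loss, VA < 0.1) and death — expanded
with the memory attributes needed to keep the process Markovian (treatment
line, last PDR therapy, permanent post-PRP visual-field-defect flag, DME
origin, SVL tenure-year tunnel states).  Each cycle accrues per-state costs
(2020 USD, split into NHIS-covered, non-covered, transportation, patient
time and care components) and utilities; both are discounted at 4.5%/year.

For strategies *s* with lifetime discounted cost C_s and effectiveness E_s
(QALYs), the package reports against the PRP-only comparator *c*:

- **ICER** = (C_s − C_c) / (E_s − E_c), with dominance labels
  ("cost-saving", "dominated") when the ratio is not meaningful;
- **NMB(λ)** = λ·E_s − C_s at willingness-to-pay λ;
- **CEAC**: Pr[s maximises NMB(λ)] across joint parameter draws, per λ.

Perspectives: *payer* (NHIS-covered medical cost only — note anti-VEGF is
not NHIS-reimbursed for PDR), *healthcare system* (covered + non-covered),
*societal* (all components, including daily care in SVL up to age 90).

Background mortality comes from a Gompertz life table
(q(x) = 1 − exp(−a·e^{bx}), a = 2.8×10⁻⁵, b = 0.09) multiplied by the
diabetes (1.49) and SVL (11.54) mortality relative risks; any two-column
`age,q` CSV can replace it.  Because the original national life table and
cycle-accounting conventions are not published, absolute costs/QALYs are
approximate by construction; the package targets the *qualitative* published
pattern, which it reproduces (see `docs/methods.md`).

## Worked example

```bash
python examples/base_case.py
```

```
== payer perspective (vs PRP-only) ==
strategy               cost     dCost     QALY   dQALY  ICER
prp-only             11,135             11.276
antivegf-only        11,039       -96   12.351   1.075  cost-saving
prp-first            11,078       -56   11.839   0.563  cost-saving
antivegf-first       11,087       -47   11.824   0.547  cost-saving

== healthcare perspective (vs PRP-only) ==
strategy               cost     dCost     QALY   dQALY  ICER
prp-only             12,769             11.276
antivegf-only        15,691     2,922   12.351   1.075  2,718 $/QALY
prp-first            14,507     1,737   11.839   0.563  3,087 $/QALY
antivegf-first       14,241     1,472   11.824   0.547  2,689 $/QALY

== societal perspective (vs PRP-only) ==
strategy               cost     dCost     QALY   dQALY  ICER
prp-only             51,405             11.276
antivegf-only        44,546    -6,859   12.351   1.075  cost-saving
prp-first            47,808    -3,597   11.839   0.563  cost-saving
antivegf-first       47,496    -3,909   11.824   0.547  cost-saving
```

Reading: anti-VEGF-only yields the most QALYs (it cures PDR faster, so
fewer patients reach severe visual loss).  From the healthcare perspective
its extra (non-reimbursed) injection cost buys QALYs at ≈ $2,700 each; from
the payer and societal perspectives the avoided SVL/DME spending and care
costs make every anti-VEGF-containing strategy cost-saving outright.

Other examples: `examples/tornado.py` (one-way sensitivity),
`examples/psa_ceac.py` (acceptability curves), `examples/microsim_check.py`
(cohort vs. 50,000-individual microsimulation), and
`examples/synthetic_inputs.py` (claims-like macro-costing and EQ-5D-style
survey generators with their estimators).  A thin CLI wraps the same
functions:

```bash
pdrcea base-case --out out/
pdrcea psa --n 10000 --seed 2020 --plot --out out/
pdrcea dsa --strategy antivegf-only --perspective healthcare --out out/
```

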