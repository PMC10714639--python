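# Parameter file schema

`load_parameters(path, fill_defaults=...)` and the CLI `--params` flag read
a flat YAML mapping of canonical parameter name → numeric value.  Unknown
keys are rejected; missing keys are an error unless `fill_defaults=True`
(the CLI always fills), in which case they take their base-case values.
Values are validated against each parameter's type (probabilities and
utilities in [0, 1], costs ≥ 0, relative risks > 0).

```yaml
# override two inputs, keep everything else at base
p_prp_success: 0.25
discount_rate: 0.03

# optional: override a parameter's PSA family or CI
distributions:
  p_pdr_to_svl:
    dist: beta
  rr_antivegf_recur:
    ci: [0.70, 1.90]
```

Canonical names (base values in parentheses):

| group | names |
|---|---|
| transitions | `p_npdr_to_dme` (0.1522), `p_pdr_to_dme` (0.179), `p_pdr_to_svl` (0.18) |
| treatment | `p_prp_success` (0.2008), `p_recur_after_prp` (0.0169), `p_dme_success` (0.534), `p_loss_followup` (0.2) |
| endophthalmitis | `p_endoph_per_injection` (0.0006), `p_endoph_treat_success` (0.595) |
| SVL continuation | `svl_continuation_y1..y5, y5plus` (0.914, 0.736, 0.65, 0.609, 0.537, 0.481) |
| relative risks | `rr_antivegf_effect` (1.75), `rr_antivegf_recur` (1.15), `rr_death_diabetes` (1.49), `rr_death_svl` (11.54) |
| annual state costs | `cost_{npdr,pdr,dme,svl}_{covered,noncovered,transport,time}`, `cost_svl_care` (11826), `cost_svl_glasses` (27) |
| episode costs | `cost_{prp,inj,endoph}_{covered,noncovered,transport,time}` |
| utilities | `u_npdr` (0.904), `u_pdr` (0.901), `u_dme` (0.912), `u_svl` (0.851), `utility_age_decline` (0.055), `disutility_pvfd` (0.01) |
| other | `discount_rate` (0.045), `wtp_threshold` (24400) |

Utility values are the age-50 anchors; the model subtracts
`utility_age_decline` linearly to age 100.  A life table is supplied
separately as a two-column `age,q` CSV (header required) via
`load_life_table` / `--life-table`.
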