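# Synthetic two-arm cohort specification transcribing the published arm-level
# summaries: sizes, full-follow-up death fractions (9/43 and 16/34), 8-month
# outpatient/inpatient cost means and SDs in TWD, utility ranges and survival
# days.  The decedent cost ratios encode the model's death-branch vs
# survive-branch cost centrals (14,804/974,976 and 597,527/1,093,309); the
# outpatient/inpatient split of decedent costs is a modelling choice (the
# source reports none), applied as the same ratio to both components.
arms:
  - name: VTD
    n: 43
    p_death: 0.2093023
    outpatient: {mean: 762109, sd: 359713}
    inpatient: {mean: 190537, sd: 282481}
    utility: {low: 0.61, high: 0.81}
    survival_days: {mean: 1187, sd: 593}
    decedent_cost_ratio: 0.015184
  - name: VMP
    n: 34
    p_death: 0.4705882
    outpatient: {mean: 920389, sd: 458914}
    inpatient: {mean: 107923, sd: 155322}
    utility: {low: 0.58, high: 0.81}
    survival_days: {mean: 853, sd: 841}
    decedent_cost_ratio: 0.546530
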