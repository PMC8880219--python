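# Key model inputs for the two-arm induction comparison (VTD vs VMP),
# transcribed from the published input table: branch probabilities (Beta),
# 8-month branch costs in TWD and branch QALYs (Gamma), each with its printed
# plausible range, plus the reported utility bounds and life-years per arm.
#
# Probability note: the printed survive probabilities equal 42/43 and 30/34,
# i.e. 1 and 4 deaths within the 8-month horizon; over the full follow-up the
# cohort table reports 9 and 16 deaths (recorded here as deaths_full_followup).
arms:
  - name: VTD
    n_patients: 43
    p_survive: {family: beta, central: 0.9767, range: [0.0, 1.0]}
    branches:
      survive:
        cost: {family: gamma, central: 974976, range: [145046, 1862083]}
        qaly: {family: gamma, central: 10.2950, range: [8.84500, 11.74500]}
      death:
        cost: {family: gamma, central: 14804, range: [0, 14804]}
        qaly: {family: gamma, central: 0.15975, range: [0.13725, 0.18225]}
    utility: {low: 0.61, high: 0.81}
    life_years: 14.1
    deaths_full_followup: 9
  - name: VMP
    n_patients: 34
    p_survive: {family: beta, central: 0.8824, range: [0.0, 1.0]}
    branches:
      survive:
        cost: {family: gamma, central: 1093309, range: [0, 1377610]}
        qaly: {family: gamma, central: 5.67950, range: [4.69800, 6.56100]}
      death:
        cost: {family: gamma, central: 597527, range: [435491, 770571]}
        qaly: {family: gamma, central: 0.06533, range: [0.05452, 0.07614]}
    utility: {low: 0.58, high: 0.81}
    life_years: 7.2
    deaths_full_followup: 16
settings:
  # GDP-per-capita willingness-to-pay threshold per QALY
  wtp_threshold: {amount: 26263.5, currency: USD, price_year: 2018}
  # TWD per USD; the source never prints its rate -- this is the 2018 annual
  # average, a documented post-publication choice
  exchange_rate: 30.16
  discount_rate: 0.03
  n_replications: 1000
  rng_seed: 2022
  wtp_grid: {max_multiple: 3.0, n_points: 41}
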