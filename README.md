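# treecea

Trial-based cost-effectiveness analysis for two-arm treatment comparisons,
built around a two-branch (survive / death) decision tree. The motivating
application is the comparison of two bortezomib-based induction regimens for
transplant-ineligible, newly diagnosed multiple myeloma — VTD
(bortezomib + thalidomide + dexamethasone, n = 43) versus VMP
(bortezomib + melphalan + prednisolone, n = 34) — over an eight-month
horizon under Taiwan's National Health Insurance, but every component is a
general health-economics building block:

- **Base case** — decision-tree expected cost and expected QALYs per arm
  (`E[C] = p·C_survive + (1−p)·C_death`, likewise for effects), incremental
  cost ΔC and effect ΔE, and the incremental cost–utility ratio
  `ICUR = ΔC / ΔE` with dominance classification on the cost-effectiveness
  plane. QALYs are utility × life-years, with utilities anchored at
  0 (death) and 1 (full health).
- **Probabilistic sensitivity analysis (PSA)** — every tree parameter drawn
  from its fitted distribution (Beta for probabilities via an
  effective-sample-size fit; Gamma for costs and QALYs via moment matching,
  with SDs derived from plausible ranges treated as central 95% intervals),
  plus a nonparametric patient-level bootstrap; both feed the same replicate
  contract.
- **Decision curves** — cost-effectiveness acceptability curve
  (CEAC: `P[λ·ΔE − ΔC > 0]` along a willingness-to-pay grid), mean
  incremental net-monetary-benefit curve `iNMB(λ) = λ·ΔE − ΔC`, and the
  CE-plane scatter with a 95% percentile box and covariance ellipse.
- **Tornado one-way sensitivity** — each parameter swept to its range
  endpoints with the rest held central, ranked by output spread.
- **Cohort statistics** — per-arm summary tables with chi-squared tests
  (Yates-corrected for 2×2) and pooled-variance t-tests, usable directly on
  printed summary rows.
- **Synthetic cohort generator** — seeded patient-level records (Bernoulli
  death, right-skewed Gamma costs, uniform utilities, log-normal survival)
  matching published arm-level summaries, because the underlying claims data
  are not deposited.

The audience is health-economics and HTA analysts who want a tested,
scriptable version of what is usually done in a spreadsheet plus TreeAge.

## Worked example

The packaged fixture `table1.yaml` transcribes the published model inputs
(branch probabilities, 8-month branch costs in TWD, branch QALYs, utility
bounds and life-years, the GDP willingness-to-pay threshold of
USD 26,263.5/QALY):

```sh
cea run --params "$(python -c 'import treecea; print(treecea.packaged_config_path())')" \
        --out cea.json
```

prints

```json
{
  "reference": "VTD",
  "comparator": "VMP",
  "delta_cost_twd": -82401,
  "delta_effect_qaly": 5.04,
  "icur_twd_per_qaly": -16351,
  "dominance": "dominant",
  "saved_twd_per_qaly_gained": 16351,
  "expected_cost_twd_VTD": 952604,
  "expected_effect_qaly_VTD": 10.06,
  "expected_cost_twd_VMP": 1035005,
  "expected_effect_qaly_VMP": 5.02
}
```

Read: at the central inputs VTD costs 82,401 TWD less and yields 5.04 more
QALYs than VMP, so it is *dominant* — every QALY gained comes with a saving
of about 16,351 TWD rather than a price. The same result in Python:

```python
import treecea as tc

arms, settings = tc.load_parameters(tc.packaged_config_path())
result = tc.compare(*arms)          # CEAResult(delta_cost=-82401., ..., dominance=dominant)
samples = tc.sample_psa(arms, settings)           # 1000 seeded PSA replicates
curve = tc.ceac(samples, settings.grid_array())   # acceptability along the WTP grid
```

Other subcommands: `cea psa` (replicate table; add `--records` for the
patient bootstrap), `cea ceac` / `cea nmb` (curves, optional `--plot`),
`cea tornado` (ranked one-way sweeps), `cea simulate` (synthetic cohort) and
`cea table2` (cohort summary with test p-values).

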