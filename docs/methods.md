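# Methods

## Model

Each arm is a two-branch decision tree over a fixed eight-month horizon:
with probability `p` the patient survives the horizon and accrues the
survive-branch cost and QALYs; with probability `1 − p` the death branch
applies. Expected values are the probability-weighted branch values; the
two-arm comparison reports ΔC, ΔE, the ICUR = ΔC/ΔE and a dominance label
(dominant / dominated / NE- or SW-quadrant trade-off / equivalent, with
"dominant" meaning weakly cheaper and weakly more effective, at least one
strictly). The ICUR is stored signed; reports additionally print |ICUR| as
"TWD saved per QALY gained" when the comparison is dominant, matching how
cost-saving comparisons are usually quoted. ΔE = 0 yields a labelled result
with no ratio rather than an infinity, so tabulation stays total.

QALYs are utility × life-years. Life-years enter as inputs (14.1 / 7.2 for
the two arms): they come from national life-expectancy tables and arm ages
outside this package's scope, and no published derivation reproduces them,
so recomputing them would be guesswork. The QALY *band* pairs each arm's
low utility bound with the other's low bound (and high with high); this
matched pairing is what reproduces the published ICUR band (17,100 and
13,538 TWD saved per QALY); a four-combination band is available via
`icur_band(..., matched=False)`.

Costs are 8-month totals in TWD (price year 2018). Because the horizon is
under a year, the deterministic base case applies no discounting; the 3%
annual `discount()` utility exists for multi-year extensions. The TWD↔USD
conversion is a single multiplicative rate; it is a required configuration
field because no official rate accompanies the source figures — the
packaged fixture uses 30.16 TWD/USD (2018 annual average), clearly marked
in the file as a post-publication choice.

## Parameter distributions

- **Probabilities — Beta, effective-sample-size fit.** `alpha = round(p·n)`,
  `beta = n − alpha` with the arm's own denominator. The fixture
  probabilities are integer event splits (42/43 and 30/34), so the fit is
  exact. A degenerate split (alpha or beta = 0) falls back to the +1
  smoothed fit with a logged warning, keeping the sampler proper.
- **Costs and QALYs — Gamma, moment matching.** `shape = (mean/sd)²`,
  `scale = sd²/mean`, which preserves the central value exactly. When only
  a plausible range is published, the SD is `(high − low)/3.92`, i.e. the
  range is read as a central 95% interval — a standard PSA convention; an
  explicit `sd:` field overrides it.
- Parameters are sampled independently: only marginals are published, so
  any correlation structure would be invented.

## Uncertainty analysis

`sample_psa` draws every parameter per replicate and rolls the tree back;
`bootstrap_patients` resamples each arm's records with replacement at its
own size and takes arm means (per-patient effect = utility × observed
survival in years, at 365.25 days/year). Both emit the same `PSASample`
contract, so CEAC, NMB curve and plane summary are computed by one code
path. Replicate RNG streams are children of one `SeedSequence`, so results
do not depend on evaluation order and are bit-reproducible per seed.

The CEAC counts replicates with strictly positive incremental NMB (a tie
counts as not acceptable; ties have measure zero under continuous
sampling). The complement curve for the comparator is `1 − CEAC`. The
default WTP grid spans 0 to 3× the GDP threshold in 40 equal steps (41
points, TWD). The plane summary reports per-axis 2.5/97.5 percentile
intervals (linear interpolation between order statistics) and the
normal-approximation ellipse from the 2×2 sample covariance at the 95%
chi-square radius; it requires ≥ 20 replicates.

A property worth knowing: with the fixture's range-derived cost SDs
(≈ 438k and 351k TWD) against a mean cost difference of ≈ −82k TWD, the
acceptability at λ = 0 — which equals P(ΔC < 0) — is about 0.57. The curve
therefore *favours* the reference arm at every price (stays above 0.5, and
above 0.95 from roughly λ ≈ USD 8k/QALY upward, including the GDP
threshold where it is ≈ 1.0), but no seed can push it above 0.95 near
λ = 0; that is a property of the published input uncertainty, not of the
sampler.

## Tornado

Ten parameters (two survive probabilities, four branch costs, four branch
QALYs) are swept one at a time to their range endpoints, others held
central — endpoints only, the classic tornado, since the tree is linear in
each parameter. The default metric is the incremental NMB at the WTP
threshold, which stays defined when a sweep drives ΔE through zero; ICUR
mode is retained and flags (rather than drops) undefined sweeps. Entries
sort by descending spread, ties alphabetically. Probabilities default to
their printed 0–1 range, reproducing the published ranking in which the
reference arm's survival dominates; `probability_range="fitted95"` sweeps
the fitted Beta central 95% interval instead.

## Cohort statistics

2×2 tables use Pearson chi-squared **with** Yates continuity correction:
the published survival p-value (0.029) matches the corrected statistic
(uncorrected gives ≈ 0.015), so that is the test the original analysis ran.
Larger tables use plain Pearson. The t-test is pooled-variance Student by
default ("independent samples t-test" in SPSS idiom) and operates on
(n, mean, sd) summaries so printed table rows are directly testable; Welch
is behind a flag. Published p-values reproduce only to the precision the
printed summaries allow (albumin 0.563 vs printed 0.560; BUN 0.663 vs
printed 0.678, the summaries being rounded where the original test saw raw
data).

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
the real claims data: per arm, Bernoulli death at the full-follow-up rate
(9/43, 16/34), independent Gamma outpatient and inpatient costs
moment-matched to the published means/SDs, uniform utilities within the
published range, and log-normal survival moment-matched and floored at one
day. Decedent costs are scaled by an arm-specific ratio (defaults implied
by the model's death-vs-survive branch cost centrals: ≈ 0.015 and ≈ 0.55)
and the arm is then re-centred by the deterministic factor
`1/((1−p) + r·p)` so the expected arm mean stays on target. The same ratio
is applied to both cost components because no decedent cost composition is
published. Not emulated: covariate correlations, censoring, cost–survival
dependence beyond the death indicator, and within-patient cost
trajectories — so pipeline tests on synthetic cohorts validate the
machinery, not clinical conclusions.

At the real arm sizes (43/34) the sampling SE of the mean cost difference
is ≈ 94k TWD against a target of −75.7k, so the sign of a single synthetic
cohort's plug-in ΔC is genuinely unstable (≈ 72% negative). The test suite
therefore checks the sign at 5,000 patients per arm, where it is
statistically guaranteed, and checks the small-cohort pipeline only for
contract properties (probabilities in [0, 1], reproducibility). Parameter
recovery is method-of-moments and is verified at 10⁵ patients per arm
(cost means within 2%, death probability within 0.01).

## Numerical and test-size choices

Suite-wide simulation sizes are chosen to keep statistical assertions
several standard errors away from their thresholds: 10⁶ draws for
distribution-mean checks (0.5% tolerance), 1000 PSA replicates (the
published replication count), 10⁵ records for recovery. Hypothesis
property tests run derandomised. Config parsing is strict (unknown keys
are errors naming their path) unless a permissive flag is passed; the JSON
schemas for both configuration formats ship in `src/treecea/data/`.
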