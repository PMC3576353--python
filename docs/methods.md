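# Methods

## Model and assumptions

A registry case is a pair `(x, t)`: calendar onset date and integer-day
delay to diagnosis. The archive closes at `t_end`; the case is registered
iff `x + t ≤ t_end`, i.e. iff `t ≤ τ = t_end − x`. Cases failing this are
absent altogether (right truncation). The estimators rest on three
assumptions:

1. **Cohort homogeneity** — the delay law does not change across onset
   cohorts, so an older cohort's cdf can be projected onto the newest one.
   This is testable (module `homogeneity`) and is the reason the reference
   cdf is fitted on one long-observed cohort rather than the pooled sample,
   which would over-represent short delays from the newest, largest cohort.
2. **Registration independent of unobserved characteristics** — every case
   with the same weighting time has the same registration probability.
3. **Closed population** — no removal (death, migration) before diagnosis.
   The generator can violate this deliberately (`removal_rate`) to probe
   sensitivity; the estimators never model it.

## Estimation

On the daily grid `u = 1..τ*` (`τ* = max τ_i`), event counts
`D*_u = Σ n_i 1{t_i = u}` and backward risk counts
`R*_u = Σ n_i 1{t_i ≤ u ≤ τ_i}` give the retro-hazard MLE
`ρ̂(u) = D*_u/R*_u` (defined as 0 on empty risk sets — no information, no
hazard) and the product-limit cdf `F̂(t|τ*) = ∏_{u>t}(1−ρ̂(u))`, computed as
a reversed cumulative product. Two exact reductions anchor the
implementation and are asserted in the tests:

- equal horizons ⇒ `F̂` telescopes to the empirical cdf;
- the fitted hazard maximizes the truncated log-likelihood
  `Σ_u [D*_u log ρ(u) + (R*_u − D*_u) log(1−ρ(u))]` coordinatewise (the
  likelihood separates over grid points).

The estimator also equals a Kaplan–Meier fit run in reverse time (right
truncation maps to left-truncated entry after `s = τ* − u`); the test suite
cross-checks against lifelines this way.

`var(F̂_t)` is the Greenwood form `F̂_t² Σ_{u>t} D*_u/(R*_u(R*_u−D*_u))`, and
the delta method gives the weight variance `var(1/F̂_t) = var(F̂_t)/F̂_t⁴`.
Grid points with `R*_u = D*_u > 0` strictly above `t` make both undefined;
the error names the offending `u`. Quantile intervals use a nonparametric
bootstrap of `(t_i, τ_i)` pairs (default 1000 replicates, seeded,
percentile method) — the published tables print percentile CIs without
stating their construction, so the bootstrap is this package's choice, not
an inference of intent.

### Weighting conventions

The registration probability of a case is `F(τ_i)` by derivation, but the
applied literature also weights at the observed delay, `F(t_i)`. Both are
first-class (`weight_mode='horizon'` / `'delay'`); horizon is the default
because it is the probability the HT estimator's unbiasedness argument
needs. The fit logs when the two disagree by more than 5%. `θ`, the
unidentifiable tail mass of the reference cdf, rescales every probability
by `1−θ` (default 0, appropriate for a reference cohort observed several
years past its onset window).

A target unit whose weighting time lies below the reference cdf's
identifiable floor has estimated probability 0 and an infinite weight. This
is an identifiability break, not a numerical accident; it raises by
default, and `exclude_nonidentifiable=True` (used by the pipeline) drops
such units with a logged count, understating the corrected count by at
least the number dropped. Weighting times beyond the reference `τ*` get
probability `(1−θ)·1`.

### Variance of the corrected rate

With `Ŵ_i = 1/((1−θ)F̂_i)`, `D` observed cases and person-years `S`,

```
var(Î) = (1/S²) Σ_i n_i var(Ŵ_i)  +  W̄² D/S² ,   W̄ = Σ_i n_i Ŵ_i / D ,
```

the first term propagating cdf-estimation uncertainty (delta-method, zero
when the reference cdf is supplied as a known function) and the second the
crude-count term scaled by the squared mean weight; with all weights 1 it
reduces to the standard crude-rate variance `D/S²`. The CI is
`rate ± z·scale·√var` (normal approximation; `z` the standard-normal
`(1+level)/2` quantile). Rates are stored at full precision; `rounded()`
reports at the 2-decimal precision customary for rates per 100,000.

**Known limitation.** The first term sums *marginal* weight variances. When
the reference cdf is estimated, all target weights share one fitted curve,
and the neglected cross-unit covariance dominates the reference-noise
contribution: in a simulation with a 400-case reference and ~1300 target
cases, the reference fit contributed roughly half the total variance of
`Î`, of which this term captured only a few percent, giving ~0.86 empirical
coverage for a nominal 95% interval. With the true cdf supplied the
interval is slightly conservative (~0.95–0.98 coverage). Users projecting a
small reference cohort should treat the CI as optimistic; a bootstrap over
the reference cohort is the pragmatic alternative.

## Back-test

`backtest_robustness` restricts to an onset cohort, truncates it at an
early closure date (horizons recomputed), HT-corrects the early-window
count (by default with a cdf fitted on that early window itself), and
compares with the cohort's count eventually observed at the late closure.
With no truncation — every horizon at least the largest observed delay —
all horizon-mode weights are exactly 1 and the estimate equals the observed
count exactly. A self-fitted early reference identifies only `F(t|τ*_early)`,
so when the delay law has mass beyond the early window's `τ*` the back-test
systematically understates (that mass is the early window's `θ`); the
simulation tests therefore use delay laws supported within the early
window when asserting unbiasedness.

## Synthetic registry

The generator draws yearly onset counts (Poisson around configured
expectations, or exact), uniform onset days within each year, and delays
independent of onset. Defaults emulate the published NRRD ALS extract:

- **Onset intensities** 2001–2007 equal the published registered counts
  (49, 75, 109, 142, 212, 347, 378) — truncation is negligible there. The
  published 2008–2009 counts (282, 73) are *already truncated*, so the true
  intensities 390 and 365 were obtained by inverting
  `observed ≈ N·E[F(τ)]` under the default delay law; the generator's
  truncated output, not its truth table, is then shaped like the published
  series.
- **Delay law**: floored lognormal with `(μ, σ) ≈ (5.739, 0.773)`, the
  closed-form least-squares match to the published quartiles 183/316/519 d
  (the three probit scores are symmetric, so `μ` is the mean log-quartile
  and `σ = (log q75 − log q25)/(2 z₀.₇₅)`). The implied median ≈ 311 d
  sits inside the published 95% CI of the median (304–334). Discrete
  Weibull and arbitrary empirical laws are available; flooring to whole
  days matches day-denominated registry tables.
- **Duplicates**: a configurable fraction (default 26/1799) of observed
  cases is re-registered with a later diagnosis date, exercising the
  keep-earliest deduplication rule.
- **Strata**: gender/age/region columns with realistic marginal mixes;
  `strata_spec` can scale delays per stratum to create controlled
  homogeneity violations.

What the generator does **not** emulate: regional differences in reporting
propensity, onset-date recall error, calendar trends in the delay law, and
informative removal. Tests passing on synthetic data therefore validate
the estimators under the stated assumptions; they do not certify those
assumptions in any real registry.

## Numerical and design conventions

- Delays are exact calendar-date differences in whole days; 0 is allowed;
  no ±1 adjustment.
- Defaults `t_end = 2009-12-21` and `min_diagnosis_year = 1993` mirror the
  emulated extract; both are parameters (the diagnosis-year cutoff is
  inclusive, and deliberately exposed because the published account of the
  boundary is ambiguous).
- Duplicate ties on the earliest diagnosis date keep the first record in
  stable input order.
- `N̂` is the integer part (floor) of the weight sum; rates use the
  unfloored sum.
- The estimation grid is daily by default; `bin_width` coarsens it by
  integer division of delays and horizons (all outputs then live on the bin
  grid).
- KS homogeneity tests run on raw delays within a common fully-observed
  window (default 1000 days from each cohort's onset-period start), where
  empirical and truncation-adjusted cdfs nearly coincide; the exact null is
  used when the smaller group has < 50 cases, and a seeded permutation test
  on the truncation-weighted cdfs is available as a sensitivity check.
- Simulation studies in the tests and the acceptance script use cohorts of
  1000–2000 cases, 60–200 replicates and 500–1000 bootstrap draws; these
  sizes make Monte-Carlo error small relative to the asserted bands while
  keeping the default suite quick to run.
- All randomness flows through `numpy.random.default_rng` seeds; fits are
  deterministic, and the pipeline stamps every output with the seed and a
  hash of the analytic configuration.
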