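# delaycorrect

Correcting rare-disease registry incidence for reporting delay.

Disease registries register a case only once it has been *diagnosed*. When
the delay between symptom onset and diagnosis is long — for amyotrophic
lateral sclerosis (ALS) the median is around ten months — the most recent
onset cohorts are systematically undercounted at any archive closure date:
cases whose diagnosis falls after closure are not late, they are entirely
absent. This is right truncation, and it makes crude incidence rates for
recent years biased downward.

`delaycorrect` implements a nonparametric correction for this
underreporting, aimed at epidemiologists and biostatisticians working with
registry extracts (one row per case with onset date, diagnosis date and
optional strata). It was built around the ALS extract of Italy's National
Registry of Rare Diseases (NRRD, onset years 2001–2009, archive closed
21 December 2009) and ships a synthetic-registry generator emulating that
setting, since the microdata are not public.

## The method

Let `T` be the integer-day delay to diagnosis of a case with onset `x`, and
`τ = t_end − x` its truncation horizon. A case is registered iff `T ≤ τ`,
i.e. with probability `1 − p₀ = F(τ)`. The reverse-time (retro) hazard

```
ρ(u) = f(u) / F(u)
```

is identical in the marginal and the right-truncated distribution of `T`,
so it is estimable from the truncated sample alone: with event counts
`D*_u = #{i : t_i = u}` and backward risk sets `R*_u = #{i : t_i ≤ u ≤ τ_i}`,
the MLE is `ρ̂(u) = D*_u / R*_u`, and the identifiable part of the cdf is the
reverse-time product-limit estimator

```
F̂(t | τ*) = ∏_{u = t+1}^{τ*} (1 − ρ̂(u)),   τ* = max_i τ_i .
```

Only `F(t)/F(τ*)` is identifiable; the unobservable tail mass
`θ = 1 − F(τ*)` is ≈ 0 for cohorts observed long enough. The cdf fitted on
an older, long-observed onset cohort is projected onto the newest cohort
(after testing cohort homogeneity with windowed two-sample KS tests), giving
each registered case a registration probability `(1−θ)·F̂(a_i|τ*)` and a
Horvitz–Thompson corrected count

```
N̂ = ⌊ Σ_i n_i / ((1−θ) F̂(a_i|τ*)) ⌋ ,
```

with `a_i` either the case's horizon `τ_i` (default, the
registration-probability derivation) or its observed delay `t_i` (the
alternative convention; both are exposed). The corrected incidence rate is
`Î = Σ Ŵ_i / S` per person-years `S`, with a Greenwood/delta-method variance
and normal-approximation CI. A back-test re-estimates a historical cohort
from its early observation window and compares with the count eventually
observed.

## Worked example

Everything below is computed, not typed in — the synthetic registry mimics
the NRRD ALS extract (yearly onset counts shaped like the registered
series, delay quartiles near 183/316/519 days, truncation at 2009-12-21,
~1.4% duplicate registrations):

```python
from delaycorrect import (SimulationConfig, simulate_registry, deduplicate,
    assign_onset_cohort, build_truncated_sample, fit_retro_hazard,
    delay_quantiles, HTIncidenceEstimator)

truth, observed = simulate_registry(SimulationConfig(), seed=42)
records, removed = deduplicate(observed)
records = assign_onset_cohort(records)

ref = fit_retro_hazard(build_truncated_sample(
    records, t_end="2009-12-21", cohort_window=("2001-01-01", "2003-12-31")))
delay_quantiles(ref, probs=(0.25, 0.5, 0.75), n_boot=500, seed=42)

target = build_truncated_sample(
    records, t_end="2009-12-21", cohort_window=("2007-01-01", "2009-12-31"))
ht = HTIncidenceEstimator(reference=ref, weight_mode="horizon",
                          person_years=124_842_678,
                          exclude_nonidentifiable=True).fit(target)
```

prints / yields:

```
observed registrations: 1641  (duplicates removed: 23)
reference cohort 2001-03: 230 cases, tau* = 3261 d
 prob  point  ci_low  ci_high  identifiable
 0.25    199   173.0    224.0          True
 0.50    319   272.0    359.0          True
 0.75    550   479.0    640.0          True
observed 2007-09 cases: 705  corrected N_hat: 1060
crude rate: 0.56  corrected rate: 0.85 (95% CI 0.77-0.93) per 100,000 person-years
true simulated incident cases 2007-09: 1095
KS 2007-09 vs 2001-03: D = 0.125, p = 0.096
```

Reading it: of the ~1095 truly incident 2007–09 cases in this simulation,
only 705 were registered by archive closure; inverse-probability weighting
by the 2001–03 cohort's delay cdf recovers 1060 — the crude rate 0.56 is
corrected to 0.85 per 100,000 person-years. The delay quantiles bracket the
generator's true quartiles, and the KS test does not reject cohort
homogeneity (the projection's key assumption).

The same pipeline is scriptable from a shell:

```
delaycorrect simulate --seed 42 --out registry.csv
delaycorrect clean    --input registry.csv --output cleaned.csv
delaycorrect fit      --input cleaned.csv --cohort 2001 2003 --out-prefix ref
delaycorrect estimate --input cleaned.csv --reference-fit ref \
                      --target-cohort 2007 2009 --person-years 124842678 \
                      --out estimate.json
delaycorrect cohorts  --input cleaned.csv --out cohorts.csv
delaycorrect backtest --input cleaned.csv --cohort 2001 2003 \
                      --early-t-end 2003-12-21 --out backtest.json
delaycorrect report   --seed 42 --out-dir run/
```

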