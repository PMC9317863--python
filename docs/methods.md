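# Methods

## Procedure

For each series and each target month the pipeline:

1. **Builds the reference design.** With month-of-year *a* and year *A*
   for the target, the reference window is the 2*w*+1 months-of-year
   centred (mod 12) on *a*; defaults *w*=3, *B*=5 anchor years, *n*=3
   seasonal blocks. The remaining 12−(2*w*+1) months-of-year, taken
   cyclically starting just after the window, are split into *n*
   contiguous blocks whose sizes differ by at most one, larger first
   (with 5 leftovers and *n*=3 the sizes are 2, 2, 1 — exact equality is
   impossible, so this deterministic near-equal rule is fixed). Every
   usable month of the anchor years enters the regression with its block
   label — not only the window months. This is deliberate: the seasonal
   block coefficients are inestimable from window-only data, and the
   inter-window months are what identify them. The current-year partial
   window *a−w..a−1* is added when those months precede both the target
   and the cutoff.
2. **Applies the exclusion cutoff.** No month after `exclusion_cutoff`
   (default 2019-12) ever enters a design. For targets after the cutoff
   the anchor years are the *B* years ending at the cutoff's year, so
   every post-cutoff target is judged against the same pre-shock era;
   earlier targets use the *B* years before their own, the ordinary
   moving-window regime. Each fit's audit record stores the latest month
   used, so cutoff compliance is checkable after the fact rather than
   assumed.
3. **Fits the quasi-Poisson baseline** log E[Y] = α + βt + γ_f by IRLS
   (log link; initial means y+0.5 so zero counts are admissible;
   convergence when the global relative coefficient change drops below
   1e−8, cap 100 iterations). Point estimates equal the Poisson MLE; the
   quasi-likelihood enters through the dispersion Φ̂ = Pearson X²/(N−k),
   floored at 1. No historical-outlier down-weighting, trend-significance
   testing, or power transformation is applied — the baseline is the
   plain quasi-Poisson fit.
4. **Predicts and classifies.** Ŷ = exp(α̂ + β̂t) (the target is in the
   reference window, the baseline factor level, so no block effect
   applies). The interval is the plug-in negative binomial with mean Ŷ
   and variance Φ̂Ŷ, i.e. size k = Ŷ/(Φ̂−1) and success probability
   1/Φ̂ — this is the only parametrization consistent with
   var(Y) = Φ E(Y); with Φ̂ = 1 exact Poisson quantiles are used. Each
   bound is the smallest integer whose CDF reaches its tail probability
   ((1−level)/2 and 1−(1−level)/2). Only observations strictly outside
   the bounds are flagged; each month is flagged marginally, with no
   multiplicity adjustment across months, so about one flag in twenty is
   expected by chance even in quiet periods.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `w` | 3 | reference-window half-width, months |
| `b_years` | 5 | anchor years of history per fit |
| `n_blocks` | 3 | seasonal blocks outside the window |
| `level` | 0.95 | two-sided interval coverage |
| `exclusion_cutoff` | 2019-12 | last month allowed into any fit |
| prediction window | 2020-06 … 2021-10 | months flagged per series |

At the defaults a post-cutoff fit uses 58 points (all of 2015-03 to
2019-12), of which 35 lie in the reference window, and estimates 5
coefficients. Counts must be integers; continuous outcomes (average
length of stay in days) are rounded half-up first — half-up rather than
banker's rounding so results are deterministic and match the everyday
convention.

## Synthetic generator

`GeneratorSpec` draws series with mean
μ_t = exp(α + βt + s_{month(t)}) × (active shock factors), where *s* is a
12-vector of month-of-year log-effects, and noise Poisson(μ) for Φ=1 or
negative binomial with variance Φμ otherwise — the same family the
detector inverts. Seasonality is specified per month, deliberately
richer than the model's block approximation, so the default panel
carries mild, realistic misspecification. The study panel emulates the
national hospital report: 80 months (2015-03..2021-10), 21
outcome-by-stratum cells with magnitudes from ~1.4×10⁶ outpatient
visits/day down to ~10³ tuberculosis-bed admissions/month, and
pandemic-era shock schedules (transient −10% outpatient deficits,
persistent −7% inpatient deficits, a +18% tuberculosis-admissions
excess, ±8% swings in LTCI stays).

What a green panel test does **not** establish: real reports have
reporting artefacts, revisions, policy-driven level shifts and
non-multiplicative shocks that the generator does not emulate; the
generator's smooth seasonality also means the fitted Φ̂ absorbs
model misfit. On the very large cells (means ~10⁶) that absorbed misfit
dominates counting noise and Φ̂ reaches the hundreds — a faithful
reflection of how the quasi-Poisson dispersion behaves on huge counts,
and the intervals widen accordingly.

## Numerical and design choices

- **Plug-in intervals.** Parameter-estimation uncertainty is *not*
  propagated into the bounds. Measured consequence (matched-family
  simulation, 58-point fits, Φ=2, 7-month trend extrapolation): coverage
  ≈ 93.2% at nominal 95%, equivalently a false-flag rate of ≈ 7% instead
  of 5%. Quantile discreteness partially offsets this at small means
  (coverage gains ~0.5pp at mean 500) but not at large ones. Users who
  need calibrated family-wise behaviour should widen `level`.
- **Block 0 as the dummy baseline.** Fitted means are invariant to the
  choice of reference category; block 0 makes the target's prediction a
  two-term closed form.
- **Trend origin** is the series' first month (0-based). Re-origining
  shifts only α̂ (verified by an equivariance test).
- **Degenerate inputs.** Empty seasonal blocks drop their column and are
  recorded in diagnostics; all-zero responses and rank-deficient designs
  raise instead of returning nonsense; fewer than 2*w*+1 window points is
  an insufficient-history error; under-dispersed fits fall back to
  Poisson intervals via the Φ̂ ≥ 1 floor.
- **Ties and bounds.** Both interval bounds use "smallest y with
  CDF ≥ q"; classification is strict beyond the bounds, so an
  observation equal to a bound is normal.

## Validation suite

`tests/test_acceptance.py` measures: interval coverage (30 000
matched-family replicates; 95 ± 2pp), IRLS agreement with an independent
generic Poisson-likelihood maximizer (25 random small designs, 1e−6
relative), coefficient-error shrinkage from N=150 to N=350 and Φ̂
recovery within 15%, window-point arithmetic (35/38) with audit-verified
cutoff compliance, ≥95% detection of factor-0.7 deficits at mean 5000,
Poisson-limit and width-monotonicity checks, and a deterministic
end-to-end CLI run. The no-shock false-flag check is held at the nominal
5 ± 2pp even though the plug-in design sits ≈ 7.3% there; it documents
the calibration gap rather than hiding it.

## Known limitations

- Monthly resolution only; no weekly windows, holidays, or
  prefecture-level stratification.
- No re-weighting of anomalous history: an outbreak inside the anchor
  years inflates the baseline (and Φ̂), masking later excesses.
- The trend term is always included and extrapolated linearly on the log
  scale; long extrapolations past the cutoff inherit its uncertainty,
  which the plug-in interval ignores.
- Flags are marginal per month; runs of flags are descriptive summaries,
  not joint tests.
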