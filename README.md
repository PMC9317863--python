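# utilsurv

Excess/deficit surveillance for monthly health-care utilization counts.

The COVID-19 pandemic changed how people used hospitals: outpatient
visits dropped, admissions fell, and lengths of stay shifted differently
by bed type. To say a month was *abnormally* low or high you need a
counterfactual baseline of what utilization would have looked like
without the pandemic. `utilsurv` builds that baseline with a
Farrington-type aberration-detection procedure on monthly count series —
the approach used in infectious-disease surveillance — and flags each
month of a prediction window as a **deficit**, **normal**, or **excess**.

It is written for epidemiologists and health-services researchers who
have nationally aggregated monthly series (e.g. converted from Japan's
MHLW monthly hospital report) and want reproducible per-month flags with
prediction intervals, plus a fully synthetic data generator so the whole
pipeline can be exercised and validated without any external data.

## The model

For a target month with month-of-year *a* in year *A*, the baseline is
fitted to reference periods: the months *a−w, …, a+w* in each of the *B*
preceding years, plus *a−w, …, a−1* of year *A* where admissible
(defaults *w*=3, *B*=5). The months-of-year outside this window are split
into *n*=3 near-equal cyclic blocks. On those historical counts Y_t a
quasi-Poisson log-linear model is fitted:

    log E[Y_t] = α + β t + f_T(t)' γ_f,        var(Y_t) = Φ E[Y_t]

where *t* is the monthly trend index and f_T(t) are block dummies
(the reference window is the baseline level). Point estimates come from
IRLS (identical to the Poisson MLE under the log link); the
overdispersion Φ is the Pearson X²/(N−k), floored at 1. The expected
value at the target is Ŷ_t = exp(α̂ + β̂t), and a two-sided prediction
interval is taken from the plug-in negative binomial with mean Ŷ_t and
variance Φ̂·Ŷ_t (exact Poisson quantiles when Φ̂ = 1). An observation
strictly above the upper bound is an excess, strictly below the lower
bound a deficit.

To keep pandemic-era data out of every baseline, a hard calendar cutoff
(default December 2019) excludes later months from all fits, and an
audit log records the latest month used by each fit so this can be
verified mechanically.

## Worked example

```sh
utilsurv simulate --seed 5 --out panel.csv
utilsurv run-study panel.csv --outdir out
utilsurv plot panel.csv --flags-dir out --outdir panels
```

`simulate` writes a synthetic 21-series panel (4 outcomes × hospital- or
bed-type strata, March 2015–October 2021) with pandemic-style shock
windows. `run-study` flags every month from June 2020 to October 2021
for each series; its summary compresses consecutive flags into ranges.
For the inpatients-per-day series, which carries a persistent −7%
suppression from April 2020, the summary line reads:

```
inpatients_per_day/total: deficit 2020-06 to 2021-10
```

i.e. every month of the 17-month prediction window fell below the lower
95% bound. An unshocked cell prints `no significant months`. The flag
table `out/flags_inpatients_per_day_total.csv` holds one row per month
(observed, expected, interval bounds, flag); for June 2020 it reads

```
date,observed,expected,lower,upper,level,flag
2020-06,1067973,1146123.23,1121130,1171387,0.95,deficit
```

— the observed count sits far below the interval, hence the deficit
flag. `out/audit.jsonl` shows `"max_month_used": "2019-12"` on every
fit, and `panels/` holds one figure per series (observed bars, bound
lines, “+” markers on flagged months).

The same `run-study` verb accepts any user-prepared long CSV with
columns `date,outcome,stratum,value` (dates as `YYYY-MM`, values as
non-negative integer counts; round continuous outcomes such as average
length of stay with `utilsurv.round_to_integer` first).

## Validation

`scripts/acceptance.py` recomputes the pipeline's headline operating
characteristic from scratch: it simulates thousands of matched-family
series (log-linear trend, block-constant seasonality, negative-binomial
noise with Φ=2), runs the full window-construction/fit/predict procedure
on each, and reports the empirical coverage of the 95% prediction
interval at the predicted month, in percent:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Heavier calibration checks (coverage, detection power, parameter
recovery, end-to-end determinism) live in `tests/test_acceptance.py`;
see `docs/methods.md` for what they do and do not establish.
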