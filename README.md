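# waterconform

Robust statistics and guard-band conformity assessment for environmental
water-quality monitoring series.

## The problem

Regulatory compliance of a watercourse is judged against specification limits
(here CONAMA Resolution 357/2005: pH in [6, 9], BOD ≤ 5 mg/L, Mn ≤ 0.1,
*E. coli* ≤ 1000 MPN/100 mL). Monitoring series are rarely Gaussian: they mix
a stable baseline with genuine pollution episodes, reporting-value plateaus,
and instrument rounding. Discarding the "outliers" throws away exactly the
temporal heterogeneity the assessment should account for. This package
implements the alternative: keep every observation, summarize the series with
outlier-resistant estimators, attach a measurement uncertainty to the robust
location, and make the compliance decision with a guard-banded rule plus an
explicit consumer's risk.

For a series `x₁…x_p` the robust scales are

```
MADe(x) = s*_MADe = 1.483 · Med|xᵢ − Med(x)|
nIQR(x) = s*_nIQR = 0.7413 · (q₃ − q₁)
```

both consistent for σ under normality, with standard uncertainty of the
median

```
u(x*) = 1.25 · s* / √p
```

and expanded uncertainty `U = k·u` (coverage factor k ≈ 2 for ~95%). The
guard band `g = 1.64·u` (5% significance) shrinks the tolerance interval
`[T_L, T_U]` to the acceptance interval `[T_L + g, T_U − g]`; the median is
declared **conform** iff it lies inside. The consumer's risk is the mass of a
normal(center, u) distribution on the far side of the tolerance limit,
estimated with 100,000 Monte-Carlo draws (a closed-form normal-tail oracle
cross-checks the estimate in the tests).

The package ships the Macaé River 2020 campaign (RJ, Brazil; 52 pH, 94 BOD,
72 Mn, and 60 *E. coli* determinations) as a built-in fixture and reproduces
the campaign's published summary and decision tables cell by cell, flagging
every cell it cannot reproduce from the printed raw data.

## Worked example

```python
from waterconform import RunConfig, run, render_table3

report = run(RunConfig(n_draws=100_000, seed=1))
print(render_table3(report))
```

```
approach,measurand,result,verdict,consumer_risk
MADe,pH,6.20 ± 0.12,conform,0.0%
nIQR,pH,6.20 ± 0.23,conform,3.6%
SD,pH,6.40 ± 0.18,conform,0.0%
MADe,BOD,4.50 ± 0.04,conform,0.0%
nIQR,BOD,4.50 ± 0.61,conform,4.6%
SD,BOD,17.2 ± 6.2,not conform,Without overlap
MADe,Mn,0.096 ± 0.008,not conform,14.3%
nIQR,Mn,0.096 ± 0.012,not conform,25.1%
SD,Mn,0.128 ± 0.020,not conform,Without overlap
MADe,Ecoli,1026 ± 36,not conform,7.0%
nIQR,Ecoli,1026 ± 35,not conform,6.4%
SD,Ecoli,1016 ± 49,not conform,25.1%
```

Reading the rows: the pH median 6.20 sits above the guarded lower limit, so
pH conforms under every approach, with a consumer's risk below 4% even for
the wider nIQR uncertainty. BOD's median 4.50 conforms despite a third of the
raw values exceeding 5 mg/L — the robust location absorbs the pollution
episodes — while the classical mean (17.2 ± 6.2) lies so far above the limit
that the interval does not even overlap it ("Without overlap"). Mn
(median 0.096 vs guarded limit 0.094/0.090) and *E. coli* (1026 vs ~971) do
not conform, with tolerance-crossing risks of 7–25%.

`report["discrepancies"]` lists every reference-table cell the computation
does not hit at printed precision (e.g. the reported BOD guarded limit
4.42 mg/L, against the computed 5 − 0.03 = 4.97), with both values side by
side.

The same pipeline is available from a shell:

```
waterconform run --fixture macae2020 --draws 100000 --seed 1 --out out/
waterconform simulate --config bod.cfg --out synthetic_bod.csv
waterconform check          # cell-by-cell reproduction ledger
```

`waterconform run` also accepts `--data FILE.csv` (columns
`measurand,value`) and `--spec LIMITS.toml` for new monitoring campaigns.

## Synthetic data

`waterconform.synthetic_data` generates series with the same fingerprint as
the real campaign — normal baseline, uniform spike contamination, an optional
mass point at a reporting value, rounding — with known truth parameters, plus
per-measurand presets calibrated against the campaign's summary statistics.
These drive the parameter-recovery and breakdown tests.

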