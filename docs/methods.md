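# Methods

## Model and procedure

The package treats a monitoring series as `p` exchangeable determinations of
one measurand whose temporal heterogeneity is part of the signal, not noise.
The analysis runs in four stages:

1. **Robust summary.** Location is the sample median; scale is estimated two
   ways, `MADe = 1.483·Med|xᵢ − Med|` and `nIQR = 0.7413·(q₃ − q₁)`. Both
   constants make the estimators consistent for σ under normality and are
   used exactly as written (1.483, 0.7413, 1.25 below) rather than at full
   precision, so results are bit-comparable with references using the
   rounded constants. The classical mean/SD route is computed alongside for
   contrast.
2. **Uncertainty.** The standard uncertainty of the median is
   `u = 1.25·s*/√p`; the 1.25 factor is the efficiency penalty of the median
   relative to the mean. Expanded uncertainty is `U = k·u`.
3. **Guarded decision.** The guard band `g = z·u` with z = 1.64 (one-sided
   5% normal quantile, used exactly, not 1.6449) shrinks the tolerance
   interval inward to the acceptance interval; the verdict compares the
   location estimate to the guarded limits, boundaries inclusive.
4. **Consumer's risk.** The measurand distribution is taken as
   normal(center, u) — a flat-prior posterior consistent with guard-band
   practice — and the risk is its mass on the far side of the tolerance
   limit from the center: probability of false acceptance when the center
   conforms, probability that the item actually conforms when it does not.
   It is estimated by Monte Carlo (default 100,000 draws, seeded); the
   closed-form normal-tail integral is kept as an independent oracle and the
   tests require agreement within four standard errors over random
   configurations.

The normality screen is a one-sample Kolmogorov–Smirnov test with location
and scale estimated from the data and no small-sample (Lilliefors)
correction. Estimated parameters make the test conservative: under a true
normal it rejects far *less* often than the nominal 5% (the property test
asserts the rate stays at or below α). All four fixture series reject
decisively despite this conservatism.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 2.0 (library), 2.05 (pipeline) | coverage factor for `U = k·u` |
| `z` | 1.64 | guard-band multiplier, 5% one-sided significance |
| `n_draws` | 100,000 | Monte-Carlo draws per decision |
| quartiles | linear interpolation (R type 7) | convention behind `nIQR` |

The reference tables bundled with the Macaé fixture are internally
inconsistent about k: most expanded-uncertainty cells imply k ≈ 2.05, one
(the *E. coli* SD cell) implies k ≈ 2.0. The pipeline defaults to 2.05,
which matches the most cells; the remainder are flagged in the report's
discrepancies section. The quartile convention is likewise not stated by the
reference; linear interpolation of order statistics reproduces the printed
interquartile ranges exactly for pH (0.870), BOD (3.095), and *E. coli*
(142), and no standard convention (R types 1–9, Tukey hinges) reproduces the
Mn cell (printed 0.0553 vs 0.0550 computed) — together with the printed Mn
median 0.0956, whose two middle order statistics are both 0.096, this shows
the reference's Mn statistics were computed from unrounded raw data that
differ from the 3-decimal printed table. Those cells are flagged, not
matched.

## Fixture reconciliation

The printed raw-data table interleaves the pH and BOD columns and yields 53
pH and 93 BOD values, against stated campaign counts of 52 and 94. The value
7.80 — the last cell of the pH block, printed on the boundary with the BOD
block — is the unique single-cell reassignment that restores both counts,
and with it every printed pH and BOD summary statistic is reproduced
exactly. The reconciled series are the default; `as_printed=True` returns
the verbatim transcription.

## Reported-precision decisions

Published compliance decisions are made from the statistics a report prints,
not from double precision. When a series carries per-statistic reporting
precisions in its metadata (the fixture does), `assess` rounds the summary
to those precisions (half-up, the reporting convention — e.g. the *E. coli*
median 1025.5 → 1026) before forming `u`, `g` and the risk. This two-stage
workflow is what reproduces the fixture's reference decision table — e.g.
the *E. coli* SD-route risk of ~25% requires mean 1016 and SD 184; the
full-precision values give 24.6%. Pass `use_reported_precision=False` for
the single-stage, full-precision analysis.

## Synthetic generator

Each value is independently: a reporting-value tie with probability
`tie_probability`; a uniform spike on `[spike_low, spike_high]` with
probability ε (`contamination_fraction`); otherwise a
normal(`baseline_mean`, `baseline_sd`) draw; then rounded. This captures the
features the decisions depend on — heavy one-sided tails, a mass point, and
rounding ties — and deliberately omits temporal autocorrelation,
seasonality, and any censoring semantics for the tie value. Passing tests on
synthetic data therefore say nothing about serially correlated series.

Presets per measurand were calibrated (population quantile analysis, then a
20-seed empirical check at n = 10,000) so that the generated median, MADe
and nIQR fall within 25% of the campaign's summary values; the spike range
compresses the real series' extremes where needed to hold the quartiles in
place (the preset targets are the three summary statistics, not the sample
extremes).

**Contamination bias.** One-sided spike contamination biases both robust
scales upward: for spikes far above a normal baseline the asymptotic
inflation of MADe is ≈ 14% at ε = 0.1 and ≈ 38% at ε = 0.2 (nIQR is
similar), because the estimators' breakdown point bounds how much
contamination they *survive*, not how far they drift. The 5%
parameter-recovery test therefore runs at ε = 0.02, where the analytic bias
(≈ 2.5%) plus sampling noise at n = 10,000 stays inside the band; the
breakdown test uses 10% replacement by 100σ spikes (robust scales move
< 25%, classical SD inflates ~30-fold). At 20% replacement the MADe shift
alone is ≈ 38%.

## Numerical choices

- Quartiles: numpy `method="linear"`; median of an even count is the mean of
  the two central order statistics.
- Reporting rounds half-up via `decimal` (regulatory convention); internal
  computation keeps full double precision.
- Degenerate inputs: constant series give zero scales (risk is then
  undefined and `assess` refuses); the KS screen errors on zero variance;
  `u = 0` in the analytic risk returns 0/1 by conformity of the center.
- A guard band that meets or exceeds the tolerance half-width raises rather
  than returning an empty acceptance interval.
- Per-decision Monte-Carlo seeds are drawn once from the master seed, so the
  full report is byte-reproducible and every decision records its own seed.
- "Without overlap" marks decisions whose `center ± U` interval does not
  intersect the tolerance interval at all; the risk is still computed and
  stored, only the rendering replaces it.

## Known limitations

- The normal(center, u) risk model presumes an approximately normal sampling
  distribution of the median; the underlying data are deliberately
  non-Gaussian, and the factor 1.25 is itself a normal-theory device.
- Reference cells traceable to unrounded source data (the Mn column) or to
  source-side rounding artifacts (the BOD guarded limit printed 4.42 vs the
  computed 4.97; a guard band printed 0.48 vs the computed 0.485) cannot be
  reproduced and are reported as discrepancies instead.
- No producer's-risk or cost-optimal guard-band machinery; one measurand per
  decision; no unit conversion (units are opaque labels).
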