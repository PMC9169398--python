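# Methods

## The model

Development toward flowering is modelled as a daily rate. For genotype *g*
on day *t* at site *s*,

RF_sgt = μᶜ + Σᵢ αᵢ·f^c_{i,sgt} + Σⱼ βⱼ·TF_{j,g}
       + Σ_{j<j*} Θ_{jj*}·TF_{j,g}·TF_{j*,g} + Σᵢⱼ γᵢⱼ·f^c_{i,sgt}·TF_{j,g} + e_sgt

with four environmental drivers f = (DL, Srad, Tmax, Tmin), each centered
on its across-site mean (12.37 h, 18.218 MJ m⁻² d⁻¹, 27.458 °C,
16.128 °C), and 12 allele operators TF_j ∈ {+1 Calima, −1 Jamapa}. The
default structure carries one QTL×QTL term (TF1×TF2) and seven QTL×E terms
(DL×TF3, DL×TF7, DL×TF12, Tmin×TF2, Tmin×TF3, Tmax×TF5, Srad×TF12): 25
fixed coefficients in all. The packaged coefficient values are the fitted
estimates for the Calima × Jamapa RI family, shipped at full precision in
`src/phenorate/data/rate_parameters_v1.tsv`.

Assumptions worth keeping in mind: the response to each driver is linear
within the environmental range of the original trials (no cardinal-
temperature nonlinearity); genetic effects are linear in the ±1 operators
of an inbred, homozygous family; and a genotype's daily rate depends only
on its 12-locus makeup and that day's weather. Extrapolated far enough
(cold, long days) the linear rate goes negative; cumulative progress would
then run backwards, so the simulator clamps negative rates to zero by
default and warns. The clamp is a policy switch (`allow-negative`) rather
than a hidden constant.

Interaction structure is data, not code: `RateModelParameters` carries
explicit θ and γ term maps, so an alternative structure fits and simulates
without code changes.

## Integration and day conventions

Flowering time is the crossing of cumulative progress P_t = Σ RF through
1.0. Integration is one Euler step per calendar day (no sub-daily steps),
day 1 being the first full day after planting, with P evaluated at end of
day. Accumulation stops once P exceeds 1.02 — a guard that guarantees a
flanking value above 1.0 — and the real-valued flowering day is the linear
interpolation between the flanking days: t−1 + (1 − P_{t−1})/RF_t. Under a
constant environment this reduces exactly to 1/RF, and the reported
integer day (first day with P ≥ 1.0) is ⌈1/RF⌉. Both the integer and the
interpolated day are always reported. The horizon defaults to 200 days;
not flowering within it is a first-class outcome, not an error.

Two candidate day-length means appear in the source material for the
sweep experiments (12.37 h vs 12.8631 h, and 18.218 vs 18.2719 MJ m⁻² d⁻¹
for radiation). We treat the first pair as the centering constants — they
reproduce the documented parental flowering days 34/38/38 under the stated
sweep settings — and the second pair as sweep *inputs* (the fixed values a
sweep holds a driver at). The long-day/low-temperature sweep extremes are
sensitive to this choice and are not treated as reference values.

## Fitting

The response is 1/TTF on the observed scale; residuals of one line across
the S sites are jointly MVN(0, R) with R unstructured. The REML (default;
ML available) objective is maximized over the Cholesky factor of R
(log-diagonal, free off-diagonals) with L-BFGS-B; the fixed effects are
profiled out by generalized least squares at each iterate. Lines observed
at a subset of sites enter through the corresponding sub-blocks of R — no
imputation. Initialization is deterministic: the pairwise-complete OLS
residual covariance with eigenvalues floored at 1e−8 of its scale.
Convergence: relative objective change below ~1e−10 (ftol 1e−11) and
projected gradient below 1e−7; infeasible covariance proposals receive a
large finite penalty so the finite-difference gradient stays defined.
Likelihood sums are accumulated in a fixed line/pattern order, making the
fit invariant to observation order to the last bit.

Centering constants are taken from configuration (the packaged means) by
default, so refits reproduce the published parameterization; recomputing
them from data is possible by passing different `CenteringConstants`, and
the CLI logs whichever were used. The model *structure* is fixed to the
published 25 terms; re-running the original variable selection is out of
scope.

The implementation was cross-validated against `nlme::gls` in R
(corSymm correlation + varIdent variances, REML) on a synthetic fixture;
coefficients agree to ~1e−6 absolute and the covariance to the printed
precision of the R output (see `tests/test_fitting.py`).

Evaluation statistics: model efficiency ME = 1 − SSE/SST; R² as the
squared Pearson correlation of observed and predicted (the 1:1-plot
usage), kept distinct from ME; adjusted R² with k = 25 fixed-effect
parameters (covariance parameters are not counted). Display rounding is
three decimals; full precision is retained internally.

## Sensitivity experiments

Temperature sweeps hold day length and radiation fixed, set
Tmax/Tmin = Tavg ± amplitude/2 (default amplitude 8 °C, grid 11–25 °C) and
simulate each genotype to a constant-environment TTF. Day-length sweeps
hold Tmax 26 °C / Tmin 18 °C / Srad 18.2719 and use a 15-point grid from
11.5 to 18.5 h. Family distributions simulate any genotype list — usually
the full 2¹² = 4096 factorial family — under one environment and summarize
the TTF distribution, counting non-flowering members separately. All sweep
cells are direct simulator calls.

## Synthetic data

The generator emulates the structure the model assumes, not any particular
season of weather:

- **Genotypes**: ±1 per locus with probability ½, independent by default;
  optional within-chromosome correlation (probability of copying the
  neighbouring locus) using the 12-locus map grouping.
- **Weather**: daily average temperature = seasonal sinusoid + AR(1) noise
  (default autocorrelation 0.6, innovation sd scaled to a 1.5 °C marginal
  sd); Tmax/Tmin split a fixed diurnal range symmetrically with a small
  positive jitter so Tmax ≥ Tmin always holds; radiation is an independent
  seasonal sinusoid floored at 0.1 MJ m⁻² d⁻¹; day length is astronomical
  (solar-declination formula, sun-center horizon convention). Five default
  profiles span warm and cool short-day tropical sites and long-day
  temperate sites, chosen so the noiseless TTF range across sites falls in
  the plausible ~27–105 day multi-site span.
- **Observations**: residual vectors across sites are drawn MVN(0, R) and
  added on the *rate* scale — the scale on which the model's residual
  enters. The day-count generator (`simulate_observations`) then reports
  R1 = round(1/rate) ≥ 1 with planting-to-R1 mean environments, matching
  how trial records are built. Its counterpart
  (`rate_scale_observations`) skips the rounding; parameter-recovery
  studies use it because rounding injects heteroscedastic noise that is
  not part of the model being recovered. The default residual sd
  (1.2e−3 d⁻¹, across-site correlation 0.3) is about 5% of a typical rate
  of 1/40 d⁻¹.

Every dataset records its `SimulationTruth` (parameters, residual model,
seed), and all generators are pure functions of configuration and seed.

What passing tests on synthetic data do **not** show: realism of weather
marginals (no weather-generator calibration), linkage maps beyond the
block-correlation option, or the behaviour of the fit under model
misspecification — the generator draws from exactly the model family being
fitted.

## Problem sizes and numerical choices

The recovery study in the acceptance tests runs 200 replicates of 150
lines × 5 sites, checking each coefficient's mean estimate against truth
at 3 Monte-Carlo standard errors; per-line mean environments are
precomputed once since only residual draws differ between replicates.
Property checks use 1000 random environment/genotype draws. Factorial
analyses use the full 4096-member family. Rate-function equality is
asserted at 1e−10 relative, the constant-environment interpolation
identity at 1e−12, noiseless recovery at 1e−8.

Known limitations: the linear rate extrapolates poorly outside the fitted
environmental range (hence the clamp); the unstructured R grows as
S(S+1)/2 and is practical for a handful of sites, not dozens; REML
standard errors of the coefficients are not reported (the recovery study
quantifies sampling variability empirically instead).
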