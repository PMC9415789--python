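# Methods

This note documents the statistical procedures implemented in `acrytrend`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate.

## Data model

The analysis unit is one *yearly mean*: a study × sampling-year ×
smoking-stratum × analyte aggregate. Published reports enter as
`StudyRecord`s carrying whatever summaries were printed (mean, median,
quartiles, range, SD — any subset), with absent cells represented as a
distinct absent state; zero is always a real measurement. Two packaged
CSV fixtures transcribe the published overview tables of European
biomonitoring studies (2001–2017 literature; HBM4EU Aligned Studies
2014–2021); transcription conventions for ambiguous printed cells are
documented beside the fixtures (`src/acrytrend/fixtures/README.md`).

## Mean and SD from order statistics

When only a median m with range [a, b] or quartiles (q₁, q₃) is available,
the mean is approximated by X̄₁ = (a + 2m + b)/4 or X̄₂ = (q₁ + m + q₃)/3
and the SD by

* n ≤ 15:  S₁ = √[((a − 2m + b)²/4 + (b − a)²)/12]
* 15 < n ≤ 70:  (b − a)/4
* n > 70:  (b − a)/6.

When both quartiles and range are printed, the quartile form is preferred:
interior order statistics have smaller sampling variance, and the
Monte-Carlo tests confirm the quartile estimator is both less variable and
less biased for right-skewed data. For log-normal data at n ≈ 90 the range
estimator overestimates the mean by roughly +29% (the extreme order
statistics spread with n), the quartile estimator sits near −8%; a
harmonized mean derived from a range is therefore a rough, bounded
approximation, not an unbiased recovery. Ranges printed as "LOD–x" with no
numeric detection limit are handled conservatively with a = 0 and the
resulting record flagged `low_confidence`.

## Trans-matrix conversion

Blood hemoglobin-adduct means (pmol/g Hb) are converted to urinary
equivalents (µg/L) by a proportionality factor fitted on paired individual
blood/urine measurements under constant exposure (heavy smokers): at zero
exposure both biomarkers vanish, so the model is zero-intercept least
squares, k = Σuᵢbᵢ / Σbᵢ², with SE and uncentered R² from the no-intercept
model (df = n − 1). The factor is fitted on all paired records regardless
of smoking status; the published two-decimal factors (1.64 for
AAVal→AAMA, 0.35 for GAVal→GAMA) are used by default for reproducibility
of the validation arithmetic, with a config switch to fit factors from a
paired-records file instead. GAVal→GAMA conversion is implemented but off
by default in panel assembly: GAMA formation depends on CYP2E1 activity,
whose polymorphism prevalence varies regionally, so a GA factor is only
valid within the population it was fitted in.

Known source discrepancy: the published validation arithmetic derives a
urinary AAMA mean of 64.5 µg/L from "median 29, range LOD–229", which the
range estimator cannot reproduce for any non-negative detection limit (a =
0 gives 71.75), and quotes a blood median of 60 where the overview table
prints 30 (the quoted downstream mean 36 is consistent with median 30:
(15 + 2·30 + 71)/4 = 36.5 ≈ 36). The package treats 64.5 as a given
reference value for the error calculation and otherwise uses the table
values.

## Inclusion rules and panel assembly

Rules are applied in a fixed order, each dropped record logged with its
rule number: (1) smoking-stratified reports only; (2) n ≥ 6 (the minimum
for validating an analytical mean); (3) an assignable sampling year;
(4) spot/morning urine in µg/L, or blood in pmol/g Hb for conversion —
24 h/12 h urine, creatinine- and per-day units are not comparable to spot
concentrations; (5) multi-year windows get the midpoint year (flagged;
an `exclude` policy is available); (6) mean estimation from quartiles or
range where no mean was published; (7) trans-matrix conversion of blood
records; (8) records flagged excluded in the source overview (overlapping
datasets). The result is permutation-invariant and idempotent. On the
packaged fixtures the non-smoker AAMA panel comprises 30 yearly means
(5509 participants): 20 aligned-study means, 2 published urine means and 8
blood-converted means. The exact membership of the source analysis cannot
be uniquely reconstructed from the printed tables, so the pipeline logs
its composition rather than asserting published totals.

## Weighted trend models

Yearly means from studies of very different size have very different
precision, so all models weight by study N (unnormalized), the assumption
being Var(yᵢ) ∝ 1/Nᵢ. No population-representativeness weighting is
applied.

*Weighted MLR.* y = β₀ + β₁·year + β₂·mean_age + β₃·pct_male, solved by
least squares on the √w-scaled design; SEs from σ̂²(XᵀWX)⁻¹ with σ̂² =
weighted SSE / (n − p); two-sided Student-t p-values. Year enters as
calendar year (slope in µg/L per year), age in years, sex as percent male.
Records missing a covariate are dropped and reported. Covariate magnitudes
on the fixture panel depend on the reconstruction above and on transcribed
auxiliary values (two mean ages are range midpoints), so the package
asserts directions and significance, not exact published coefficients.

*LOESS.* At each grid point the ⌈span·n⌉ nearest observations are weighted
by tricube(d/h) (h = distance of the k-th nearest) times the study weight,
and a local polynomial is fitted; defaults span 0.75, degree 2, no
robustness iterations (the conventional defaults of the method). Local
degree-d fits reproduce global degree-d polynomials exactly, which is the
main correctness oracle; the smooth is translation-equivariant in x.

*Segmented regression.* y = β₀ + β₁t + β₂(t − ψ)₊ (year-only by default;
covariates optional). ψ is estimated by iterative linearization: augment
the design with U = (t − ψ)₊ and V = −1[t > ψ], update ψ ← ψ + γ̂/β̂₂, stop
at |γ̂| < 1e−6 or 100 iterations. The weighted-SSE profile in ψ is
piecewise smooth and can be multimodal, and its minimum can sit exactly on
an observed year (a knot), so the implementation also evaluates a
0.05-year grid that includes the interior knots and keeps whichever
solution has the lower SSE; `method` records whether the iteration
("muggeo") or the grid supplied the estimate. se(ψ) = se(γ̂)/|β̂₂|.
df = n − 4 for the year-only model (β₀, β₁, β₂ and ψ all estimated).

*Breakpoint existence test.* The test statistic is
F = [(SSE_linear − SSE_segmented)/2] / (SSE_segmented/df). Because ψ is
chosen to minimize SSE, F has no standard null distribution; the p-value
comes from a parametric bootstrap under the fitted no-breakpoint weighted
linear model: simulate responses with errors N(0, σ̂²/wᵢ), re-minimize over
ψ for each replicate (vectorized grid over the same candidate set), and
report p = (1 + #{F* ≥ F_obs})/(n_boot + 1), so p ≥ 1/(n_boot + 1) by
construction. Type-I error of this test on linear panels is verified to
sit near the nominal level. Davies' test is deliberately not implemented.

*Residual diagnostics.* Standardized weighted residuals √wᵢ rᵢ/σ̂ paired
with normal plotting positions Φ⁻¹((i − ½)/n), exported as a table for
Q-Q inspection; a numerically perfect fit standardizes to all zeros.

On the fixture panel the weighted MLR gives a year slope of +1.74 µg/L per
year (p = 6e−05) and an age slope of −0.59 (p = 8e−04); the segmented fit
places the breakpoint at ψ = 2017.0 with slopes +3.1 before and −6.2
after, p_break = 0.006 at 499 bootstraps (seed 0). These are the package's
own reconstructed values, not assertions about the source analysis.

## Synthetic-data generators

All generators use `numpy.random.default_rng` (PCG64); identical seeds
give identical bytes.

*Paired dual-matrix records* (`gen_dual_matrix`): blood levels are
log-normal per stratum (non-smoker median 27 pmol/g Hb, smoker 80,
σ_log = 0.4 — smokers' constant higher exposure is what makes the factor
fit feasible), 24 subjects with 13 smokers by default; urine = slope ×
blood × mean-one log-normal noise at CV 20%. Mean-one (rather than
median-one) noise keeps E[urine | blood] exactly proportional, so the
least-squares slope is unbiased for the generating slope. A single
24-subject draw still carries a sampling SD of roughly 6–9% in the
recovered slope (the b²-weighting of the zero-intercept estimator lowers
the effective sample size), which is why recovery is assessed within 3 SE
and why the acceptance script averages over replicate scenarios.

*Individual studies* (`gen_individual_study`): n log-normal values
reported only as order statistics, with the hidden sample mean returned
separately; n < 6 is rejected to mirror the inclusion rule.

*Yearly panels* (`gen_panel`): per study, N ~ uniform(6, 857) — the span
of study sizes in the source overview — mean age and percent male uniform
over configurable ranges, true mean following a broken line (defaults:
intercept 40 µg/L in 2001, +2.1 µg/L/yr to a 2017 breakpoint, −6 µg/L/yr
after it, matching the decline the harmonized panel itself exhibits), and
observed mean = truth + N(0, sd/√(n/100)) with sd = 8 µg/L at n = 100,
truncated at zero. The 1/√n noise makes N-weighting the efficient choice,
mirroring the weighting rationale of the analysis. Truth values live in a
separate JSON sidecar and never appear in the emitted panel files.

What the generators do *not* emulate: regional heterogeneity in levels and
in GAMA/AAMA ratios, creatinine/urine-density dynamics, correlated
repeated surveys from the same country, non-uniform study-size
distributions, or reporting heterogeneity (every synthetic study reports a
mean). Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed sampling structure, not robustness to the
full messiness of the published literature.

## Numerical choices and limitations

* Bootstrap replicates re-minimize ψ by vectorized grid search over the
  same candidate set as the fallback optimizer; the observed statistic
  uses the full (iterative + grid) fit. Grid resolution 0.05 years.
* p-values are clipped into (0, 1]; degenerate zero-variance designs raise
  a collinearity error naming the offending column.
* The smokers' trend uses the same WLS machinery as the non-smokers'
  (no separate correlation structure is modelled).
* No between-study variance component (meta-regression) is modelled: the
  weighting assumes all heterogeneity scales as 1/N, which understates the
  uncertainty of small outlying studies.
* Single breakpoint only; multiple-breakpoint search is out of scope.
* Test-suite simulation sizes (e.g. 50-seed type-I check at 99 bootstraps,
  1000-replicate estimator bias checks) are chosen to give stable verdicts
  at interactive runtimes.
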