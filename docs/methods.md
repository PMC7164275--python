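# Methods

## Agreement model

All repeatability statistics are built on the balanced one-way
random-effects model for an n-subjects × k-replicates table:
X_ij = μ + b_i + e_ij, b_i ~ N(0, σ²_B), e_ij ~ N(0, σ²_W). The columns
carry no structure of their own (single operator, single instrument,
exchangeable replicates), which is why the one-way, single-measurement ICC
— rather than a two-way variant — is the estimand:
ICC = σ²_B/(σ²_B + σ²_W). Estimation is by method of moments,
ICĈ = (MSB − MSW)/(MSB + (k−1)MSW). The estimator may be negative; it is
reported unclamped because clamping at zero would bias upward every
simulation summary in the low-ICC regime, and the qualitative benchmark
(poor ≤ 0.20 < fair ≤ 0.40 < moderate ≤ 0.60 < substantial ≤ 0.80 <
excellent; half-open intervals close the gaps of the conventional scale)
maps any negative value to "poor" anyway.

The significance test of H0: ICC ≤ ρ₀ refers
F = (MSB/MSW)·(1−ρ₀)/(1+(k−1)ρ₀) to F(n−1, n(k−1)), one-sided; with
ρ₀ = 0 this is the classical one-way ANOVA F test. Confidence intervals
use the exact F pivot (Searle): lower/upper limits
(F/f_{1−α/2} − 1)/(F/f_{1−α/2} + k − 1) and the symmetric counterpart.
Degenerate inputs: MSW = 0 with MSB > 0 yields estimate 1, F = ∞, p = 0;
an entirely constant table raises an agreement-undefined error rather than
fabricating 0/0.

CVs use the sample SD (denominator length − 1) everywhere and require a
strictly positive mean — the CV is only meaningful on a ratio scale. The
acceptability rule (mean per-subject CV < 0.15) is strict: exactly 0.15
fails. The pooled CV treats all n·k values as one sample; it absorbs
between-subject spread and is therefore the quantity the second simulation
batch tracks (see below). Missing data are rejected, never imputed;
callers drop incomplete subjects explicitly.

Bland-Altman agreement takes differences first − second (baseline minus
follow-up in the pipeline). The default limits are nonparametric — the
5th/95th percentiles of the differences under one fixed percentile
dialect: linear interpolation between order statistics at rank
1 + (p/100)(m−1), identical to numpy's default, declared once and used
everywhere so the sorting oracle in the tests is exact. A parametric mode
(bias ± 1.96 SD) is available. Because visual heteroscedasticity checks do
not compose into a pipeline, a numeric companion is provided: two-sided
Spearman rank correlation of |difference| against the pairwise mean at
α = 0.05; when it fires and the data are positive, the pipeline re-runs
the analysis on the log scale and reports both. With fewer than ~20 pairs
the rank test is very low-powered and can be degenerate (constant
|differences| return ρ = 0, p = 1 by convention).

## Sample-size planners

The ICC planner implements Zou's formula
n = 1 + 2k(z_a + z_b)²/[(k−1)(ln(C₁/C₀))²] with C(ρ) = (1+(k−1)ρ)/(1−ρ),
derived from the asymptotic variance 2k/[(k−1)(n−1)] of the log F ratio;
n is always the ceiling of the real solution. The tail convention is an
explicit parameter (default two-sided): the two canonical designs
(k = 5 → n = 10; k = 2 → n = 21, both for ρ₀ = 0.20 vs ρ₁ = 0.70 at 90%
power) are mutually consistent only with two-sided and one-sided critical
values respectively, so the choice is surfaced rather than hidden.

The Bland-Altman planner finds the smallest n for which, with the
requested power (default 0.80 at α = 0.05), both estimated 95% limits of
agreement together with their one-sided confidence bounds fall inside a
symmetric ±δ region. It uses the normal approximation
SE(m̂ + 1.96 ŝ) ≈ σ√(1/n + 1.96²/(2(n−1))) and treats the limit nearer the
boundary as binding; the neglected opposite tail makes the approximation
mildly optimistic when the mean difference is 0, which the Monte-Carlo
power oracle in the test suite bounds (measured power 0.79 at the returned
n = 18 for mean 0.20, SD 0.10, δ = 0.50). The planner requires
|μ| + 1.96σ < δ; otherwise the true limits already violate the region and
no n suffices.

## Simulation batches

Batch 1 (fixed true CV, ICC estimated): subject means are the *fixed*
grid of 10 equally spaced values from 5 to 8 — not redrawn per replicate —
and each subject's k = 5 values are Normal(μ_i, μ_i·cv) for each of 50 cv
values from 0.01 to 0.99, 1000 replicates per cell. The one-way ICC
estimate of each replicate dataset is averaged per cell. Because the
between-subject spread is deterministic, the cell means track the design
ICC V_μ/(V_μ + cv²·M_μ) (V_μ the variance, M_μ the mean square of the μ
grid). The method-of-moments estimator carries a small negative bias at
n = 10 — measured at −0.004 to −0.007 for cv between 0.25 and 0.5 at
40 000 replicates — which the analytic-check test accommodates with a
0.008 allowance on top of Monte-Carlo error; negative estimates enter the
means unclamped.

Batch 2 (fixed true ICC, CV estimated): for each overall mean γ ∈ 1..10,
between-subject SD σ_B ∈ {1, 2, 3} and true ICC ∈ 0.1..0.9, the within
SD is σ_W = σ_B√((1−ICC)/ICC); subject means are Normal(γ, σ_B) and
values Normal(mean_i, σ_W). The summarised index is the *pooled* CV (SD
of all 50 values over the grand mean): the published grid is numerically
consistent with the pooled definition (e.g. √2/10 ≈ 0.141 at
σ_B = σ_W = 1, γ = 10, printed 0.138) and not with the per-subject one
(≈ 0.094); a per-subject mode is exposed for sensitivity analysis.
Negative draws and negative grand means at small γ are kept — the ratio
estimator is genuinely heavy-tailed there, which is the point being made —
so the batch computes the ratio inline without the positivity guard that
the public `cv_pooled` enforces. Small-γ cells are qualitative only; at
γ = 10 the cell means approach the delta-method limit √(σ²_B+σ²_W)/γ, with
a known second-order positive bias of about +0.015 at the single heaviest
cell (σ_B = 3, ICC = 0.1, total CV ≈ 0.95).

Randomness: one root seed; each grid cell uses the substream
`SeedSequence(seed, spawn_key=(cell_index,))` with cells enumerated in the
documented grid order, so full and partial grids agree bit-for-bit.

## Synthetic study generator

The generator emulates the clinical design — 5 diagnosis groups
(HC, NAR, PAR, SAR-O, SAR-D) × 10 children; four resistance parameters
(R2, R75, R100, R150) × two phases × two nostrils, with TOT = R + L
record-wise (arithmetic sum, consistent with the additivity of the
published combined totals); five baseline replicates and one measurement
at days 14 and 28 — with configurable ground truth. Per (subject,
parameter, phase, side) the model is two-level: total variance calibrated
to the published group mean ± SD of the combined resistance (per side:
mean/2 and SD/√2, symmetric independent nostrils), split as
between = ICC·total and within = (1−ICC)·total.

The default noise family is lognormal with moment-matched log-scale
parameters, because resistances are positive and the published SDs are of
the order of the means (8.85 ± 11.77 in the most extreme group) — a
normal model would put substantial mass below zero. The normal mode exists
to match the simulation batches' assumptions exactly for
estimator-recovery tests; it does emit occasional nonpositive values,
which the CV operations reject by design and the pipeline records as
CV-unavailable for the affected key while still reporting the ICC.

Follow-up visits add (a) a day-level random effect scaled as
`day_sigma_frac` (default 0.5) of the within-SD, so between-day ICC falls
below within-day ICC as observed in real studies, and (b) an optional
multiplicative drift per visit; SAR-D defaults to drift 0.8, emulating
resistance regressing as the pollen season wanes. Default true ICCs
(HC 0.50, NAR 0.55, PAR 0.85, SAR-O 0.80, SAR-D 0.75) sit in the range of
the published within-day estimates; they are conveniences for realistic
data, not claims about the cohort. Symptoms are Bernoulli with the group
prevalence (0.60/0.80/0.90/1.00/1.00), tilted — for groups with prevalence
strictly inside (0,1) — by a logistic link (slope default 1.0) on the
subject's standardised latent R2 level, giving cohort AUCs near 0.7, in
the range of the published ROC table. The T5SS score and anthropometrics
are generated only so the descriptive stage has realistic covariates.

What the generator does *not* emulate: pressure-flow curve mechanics,
nostril asymmetry, therapy effects, item-level symptom dynamics, and any
within-subject correlation between the four resistance parameters beyond
what the shared symptom link induces (each parameter/phase/side gets an
independent latent). Tests passing on synthetic data therefore validate
the *estimators and pipeline plumbing*, not any claim about real cohorts.

## Pipeline conventions

Within-day repeatability runs per (group, parameter, phase, side),
including combined-total rows (total inspiratory + total expiratory,
arithmetic sum). The day-0 value used for between-day comparisons is the
mean of the five baseline replicates (configurable to the first
replicate); between-day tables use the combined totals, one-way ICC at
k = 2, the mean two-point CV |a−b|/(√2·mean), and nonparametric
Bland-Altman. The ROC predictor is the subject's baseline mean of the
chosen total; the outcome is the binary current-symptoms indicator; the
cross-validated AUC uses stratified folds (default 5, seeded) with the raw
parameter as score — no classifier is fitted, matching the single-variable
design. p < 0.05 is reported as significant and no multiple-testing
correction is applied anywhere, deliberately mirroring the convention of
the motivating analysis; interpret the 140-row tables accordingly.

Every ICC/CV/Bland-Altman number in pipeline output is produced by calling
the core agreement operations on the extracted sub-table; the test suite
asserts bit-identity.

## Numerical and testing notes

* Percentiles, SDs (ddof = 1), and the percentile dialect are fixed
  package-wide; tests use independent oracles (double-loop sums of
  squares, numerical F-density integration, exhaustive pair counting,
  direct placement values, sort-and-interpolate percentiles).
* DeLong intervals are Wald intervals on the AUC scale clipped to [0, 1];
  at n = 100 with balanced classes their null coverage is ≈ 0.943
  (measured over 10 000 simulations) — the usual mild anti-conservatism of
  Wald intervals.
* Simulation-heavy tests run at reduced replicate counts (200–400) chosen
  so Monte-Carlo error stays well below the asserted tolerances; the two
  full 1000-replicate batches run once each (seconds, vectorised) in the
  acceptance tests.
* The nonparametric limits bracket ≥ 90% of differences up to one
  interpolation point per tail (the 1/m edge effect the percentile
  definition implies).
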