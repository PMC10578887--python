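# Methods

## The trichotomy model

Each subject is placed in a three-dimensional biomarker space whose axes
are a raw Alzheimer's disease factor, a raw vascular disease factor, and a
raw cognition score, each a fixed linear rule over transformed inputs:

* `ADF_raw = log10(pTau / Aβ42)`, CSF concentrations in pg/mL, cutoff
  `c_th = log10(0.022)`. The ratio form captures the joint signature of low
  Aβ42 and high pTau; the cutoff is the value concordant with amyloid-PET
  positivity.
* `VDF_raw = 0.135·log10(PSMD·10⁴) + 0.991·log10(mFW·10²) − 1.474`,
  cutoff 0. mFW is the mean free-water fraction in white matter
  (dimensionless, order 0.15–0.35); PSMD is in mm²/s (order 2–4·10⁻⁴). The
  scale factors bring the log arguments to order 1 and are part of the axis
  definition so callers cannot introduce silent unit errors.
* `Cog_raw = −0.076·ADNI_EF − 0.997·ADNI_MEM + 0.519`, cutoff 0; larger
  means worse cognition. ADNI_MEM/ADNI_EF are standardized composite
  memory/executive scores.

The VDF and Cog rules are two-class Fisher discriminants; `fit_lda_axis`
reproduces that construction for user data: pooled within-class covariance,
equal priors, weight vector `w ∝ Σ⁻¹(μ_patient − μ_control)` rescaled to
unit Euclidean norm (both published coefficient vectors satisfy
`‖w‖₂ = 1` to three decimals), oriented so the patient class projects
positive, intercept placing the projected midpoint of the class means at
zero. With equal priors this midpoint is the Bayes boundary of the
projected model, which is what makes `c_th = 0` meaningful. A singular
pooled covariance receives a ridge `εI`, `ε = 10⁻⁶·mean(diag Σ)`, with a
warning; identical class means are an error rather than a silently
arbitrary axis.

## Uniform normalization transform (UNT)

Raw scores live on incommensurate scales, so each axis is normalized by a
monotone map to (0,1) that sends its cutoff to exactly 0.5. The transform
is table-based and has three binding properties: outputs strictly inside
(0,1), cutoff → 0.5, and approximate uniformity of the calibration sample
on each side of 0.5. The construction here is the minimal such map — a
piecewise-affine rescaling of the empirical CDF around the cutoff:

1. Tabulate `F`, the empirical CDF of the calibration scores at their
   sorted unique values, with midrank tie handling and the
   `(rank − ½)/n` convention (keeps tabulated values strictly inside
   (0,1)); interpolate linearly between knots.
2. With `F₀ = F(c_th)`, map `x ≤ c_th` to `½·F(x)/F₀` and `x > c_th` to
   `½ + ½·(F(x) − F₀)/(1 − F₀)`; the cutoff knot is pinned to 0.5 exactly.

This is a deliberate reconstruction: only the three properties above are
specified for the published transform, and any monotone map satisfying them
is equivalent up to within-half reparametrization. Rank order, and hence
every subgroup assignment, is invariant to that choice; the exact
normalized value between knots is not.

Calibration requires ≥ 20 finite values, non-degenerate support, and the
cutoff strictly inside the calibration range (both halves must be
populated). Tables are calibrated once, serialized as two-column plain text
(bit-exact round trip), and applied to new subjects without refitting. A
new subject outside the calibration range is clamped to `ε = 1/(2n)` or
`1 − ε`, symmetric with the CDF convention; the event is logged. Ties
exactly at the cutoff count as negative, consistent with the
classification rule below.

## Classification

An axis is called positive iff its normalized score is strictly greater
than 0.5 (a score exactly at the threshold is negative, matching the
"≤ 0.5 vs > 0.5" split of the cognition dichotomy). The sign triple
(Cog, ADF, VDF) indexes the eight subgroups; because the UNT is
mass-preserving around the cutoff, the fraction of a calibration cohort
positive on an axis equals the fraction with raw score above that axis's
cutoff. Reported percentages are rounded half-up to one decimal; note
73/538 = 13.568% rounds to 13.6.

## Statistical battery

* `partial_correlation(x, y | Z)` is the Pearson correlation of the OLS
  residuals of x and y on Z (intercept always included; categorical
  covariates dummy-expanded; default covariate set: age, sex, education,
  protocol). The p-value uses `t = r√(df/(1−r²))` with `df = n − 2 − k`.
  The accompanying slope/SE come from the OLS of y on x plus Z. P-values
  are floored at 10⁻³⁰⁰.
* `compare_models_aic` reports `R² = 1 − RSS/TSS` and the Gaussian-profile
  AIC `n·ln(RSS/n) + 2(k+2)`, k = number of predictors (+2 for intercept
  and error variance). The additive constant is a convention; only AIC
  differences within a response are meaningful. Note AIC is not a
  consistent selector: adding one pure-noise predictor wins whenever its
  deviance gain exceeds 2, asymptotic probability `P(χ²₁ > 2) ≈ 0.157`, so
  the true smaller model is preferred in ≈ 84% of replicates regardless of
  n. Plain R² never decreases under nesting; if a penalized quantity is
  wanted, use the AIC column.
* The group battery tests nine hypotheses over auxiliary variables (male
  proportion, any/both APOE4 alleles, CDRSB > 0 and ≥ 1, ΔCDRSB/yr > 0 and
  ≥ 0.5 as proportions; hippocampal volume and brain atrophy as means)
  across nine subgroup-union contrasts (overall cognition, VD, AD, and the
  six conditional versions). Proportions use the chi-squared test without
  Yates continuity correction; means use the pooled-variance two-sample
  t-test (Welch available via `welch=True`); both choices are documented
  conventions since either variant is defensible. Bonferroni correction
  multiplies by the full battery size 9 × 9 = 81, capped at 1. A 2×2 table
  with an empty cell is reported as untestable rather than given a p-value.
  The hypothesis set is configurable; the default battery of nine is the
  package's own concretization of "proportion and mean contrasts over the
  six auxiliary variables", since only the variable list and the count of
  nine are fixed.

## Synthetic cohort generator

The generator emulates an ADNI-like table with known ground truth: latent
Bernoulli states AD (prevalence 0.40) and VD (0.18) shift log-normal
biomarkers (Aβ42 down / pTau up under AD; mFW and PSMD up under VD);
within-pair correlations come from shared latent factors (mFW–PSMD ρ≈0.7,
Aβ42–pTau negative, MEM–EF ≈0.5). Cognitive impairment is a third latent
Bernoulli whose probability rises with each disease state
(0.15 + 0.55·AD + 0.30·VD), and the cognition composites are linear in
impairment, the disease states (AD hits memory harder, VD hits executive
function harder), age, and Gaussian noise. Auxiliary variables (APOE4,
CDRSB, ΔCDRSB, hippocampal volume, atrophy, clinical label) are coupled to
the same latents. Default location/scale values put the healthy modes at
Aβ42 ≈ 1400 pg/mL, pTau ≈ 18 pg/mL, mFW ≈ 0.16, PSMD ≈ 2·10⁻⁴ mm²/s —
typical published control values — with the disease shifts sized so the
default cohort shows realistic overlap across each cutoff (≈ 1–1.5 SD
margins), i.e. classification from the generated biomarkers is imperfect
by design. `strong_effect_config` widens every margin to ≥ 2–3 SD for
end-to-end recovery tests where the latent truth should dominate.

What the generator does **not** emulate: scanner/protocol measurement
artifacts beyond a categorical protocol covariate, inclusion/exclusion
selection effects, longitudinal structure, non-Gaussian heavy tails, and
informative missingness. Passing recovery tests therefore show the
pipeline's correctness under the stated generative model, not performance
on real data.

## Numerical and design choices

* Boundary ties: score = threshold → negative, on all three axes.
* Percent rounding: decimal half-up (not banker's), one decimal.
* UNT serialization uses `repr` of Python floats for bit-exact reload.
* LDA at n = p + 2 is allowed but noisy; recovery guarantees in the tests
  are stated at n ≥ 1000/class.
* Leave-one-out accuracy of the LDA rule is pessimistically biased when
  the true effect is null (excluding the held-out subject moves its own
  class mean away from it), so null-case LOOCV sits at or below 0.5 —
  around 0.41 at n = 200 and far lower at small n. It is a stability
  check for clearly separated classes, not an unbiased null-accuracy
  estimator.
* Pipeline problem sizes: recovery checks run at 2000 subjects, the
  normalization invariants at 10⁴ calibration points, and the null
  family-wise-error simulation at 500 replicates of 120 subjects — sizes
  at which the binomial/KS error bands are comfortably narrower than the
  margins being asserted.

## Known limitations

* The exact functional form of the published normalization between knots
  is underdetermined (see above); subgroup assignments are unaffected.
* The battery's nine default hypotheses are a reasonable concretization,
  not a published list; analyses replicating a specific study should pass
  their own `HypothesisSpec` set.
* Cohort-specific regression tables and accuracies from access-controlled
  data are out of scope; the package validates those code paths on
  synthetic cohorts with known ground truth instead.
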