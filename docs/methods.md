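# Methods

## Detection model

Each entry of a feature-by-sample log2-intensity matrix is detected
independently with probability logit⁻¹(β0 + β1·y), where y is the entry's
underlying log2 intensity and (β0, β1) are global across features and
samples. β1 ≥ 0 is assumed throughout (detection cannot become less likely
as abundance grows). The model nests the usual taxonomy: β1 = 0 is MCAR,
large β1 approaches left-censoring at −β0/β1.

Features missing in all n samples are invisible, so the per-feature
detected count is modelled as zero-truncated binomial ZB(n, p_i). All
curve fits maximise the zero-truncated likelihood; its gradient in the
linear predictor is d_i − n·p_i/(1 − (1−p_i)^n), which is supplied
analytically to an L-BFGS-B optimiser (iteration cap 200, ftol 1e−12,
gradient tolerance 1e−8, probabilities clamped to [1e−12, 1−1e−12]).
Starting values come from an untruncated binomial GLM of d_i/n on the same
predictor. Standard errors are from the numerically differentiated
observed information at the optimum.

Three curve variants are fitted to the per-feature detection proportions:

* **Logit splines on observed means** (df 1, 3, 5). The basis is a natural
  cubic spline in the truncated-power construction, df−1 interior knots at
  equal-count quantiles of the observed feature means, boundary knots at
  the data range, linear beyond the boundary. The basis spans the same
  space as R's `ns()`, so likelihoods and the deviance decomposition are
  invariant to the (non-orthogonalised) representation. The deviance table
  splits 2·(ℓ_df5 − ℓ_intercept) into the linear share and the df=3 and
  df=5 increments; the shares telescope to 100% by construction.
* **Capped logit-linear**: p_i = α·logit⁻¹(β0 + β1·ȳ_i) with asymptote
  α ∈ (0, 1] estimated on the logit scale (bounded at logit α = 13.8,
  i.e. α within 1e−6 of 1). If the optimiser reaches that bound the model
  is refitted with α fixed at 1 and flagged as a boundary solution rather
  than an error.
* **Underlying-intensity (bias-corrected) DPC.** Observed feature means
  over-represent each feature's high-intensity tail. Under normality the
  marginal log-odds of detection is β0 + β1·μ_obs − ½·β1²·σ², so the
  logit-linear fit uses ȳ_i − ½·β1·σ̂²_i (times β1) as its effective
  predictor, with σ̂²_i the moderated variance (below). This is a single
  corrected maximisation — the correction lives inside the likelihood —
  not an outer fixed-point loop over the missing-value mean; the two
  agree in the cases we examined and the single pass is simpler and
  convex-friendly. When all σ̂²_i = 0 the fit collapses exactly to the
  observed-mean logit-linear fit.

Sampling noise in the plug-in means ȳ_i (variance σ²/d_i) acts as
classical measurement error on the predictor, so the slope is attenuated
very slightly toward zero (≈0.005 at the simulation's settings) with a
compensating intercept shift; the acceptance band accounts for this
scale of Monte-Carlo and plug-in error.

## Variance moderation

Per-feature sample variances are shrunk by the standard empirical-Bayes
scaled-inverse-chi-square scheme: the prior (d0, s0²) is estimated by
moment matching on log variances (digamma/trigamma corrections with a
Newton inversion of the trigamma function), and the posterior is the
precision-weighted combination (d0·s0² + df_i·s²_i)/(d0 + df_i). Exact-zero
variances are offset to 1e−5 times the median before taking logs. When the
observed log-variances are no more dispersed than sampling noise alone the
prior degrees of freedom are infinite and the prior scale reduces to the
arithmetic mean of the variances. The implementation reproduces
Bioconductor limma's `squeezeVar`/`eBayes` to machine precision on shared
inputs (checked in the test suite via Rscript); features with no residual
information receive the prior variance.

For DPC fitting the variance comes from deviations about a single feature
mean; for differential expression it is the residual variance of the
group-means model. Differentially expressed features inflate the former
slightly (their two group means are pooled), which is accepted — the same
approximation underlies fitting the curve to feature-level detection
proportions at all, and most features are assumed non-DE.

## Exponential tilting and information content

Bayes' theorem links the missing-value density to the observed one:
f_mis(y) = e^{−β1·y}·f_obs(y)/M_obs(−β1). For normal f_obs this gives
N(μ_obs − β1·σ², σ²) in closed form; a grid-based tilt (uniform grid,
trapezoid normalisation) handles tabulated densities and refuses grids
whose boundary mass exceeds 1e−8. The Fisher information comparison
I1 = n·p/σ² (observed intensities) versus I2 = n·β1²·p(1−p) (missingness
count) gives the ratio β1²(1−p)σ²: with σ² around 0.1 and moderate
missingness, counts carry an order of magnitude less information than
intensities, which is why the likelihood test below yields a modest, not
dramatic, power gain.

## Differential expression

Two pipelines share the moderated variances:

* **Moderated t** on observed values only: per-feature two-group linear
  model, shrunk residual variance, t reference with df_i + d0 degrees of
  freedom (capped at the pooled residual df). Features need ≥1 observation
  per group and ≥3 overall; others are NA.
* **DPC likelihood-ratio test.** Fixed plug-in (β0, β1) estimated once
  globally, per-feature σ² fixed at its moderated value. The per-group
  log-likelihood is Σ_obs log N(y; μ_g, σ²) + m_g·log p(d=0; μ_g, σ²),
  where the missing-value probability integral is evaluated by
  Gauss–Hermite quadrature with 32 nodes after centring/scaling to
  (μ, σ). Thirty-two nodes keep the absolute log-scale error below 1e−8
  against adaptive dense integration across μ ∈ [5, 12], σ² ≤ 1,
  β1 ≤ 1.5 (16 nodes bottom out near 4e−7 at the wide-variance corner).
  Null (shared mean) and alternative (per-group means) are maximised by a
  damped Newton iteration vectorised across features — the objective is
  strictly concave whenever a group has at least one observed value, and
  the vectorised optimum matches per-feature brute-force optimisation to
  1e−12. The statistic 2(ℓ_alt − ℓ_null) is referred to χ²₁, negative
  round-off is clamped at −1e−8, and BH adjustment is applied across
  tested features.

  By default a feature is testable when each group has ≥1 observed value.
  Features observed in only one group are genuinely informative (an
  all-missing group suggests down-regulation), but the empty group's
  likelihood supremum is attained in the μ → −∞ limit — a boundary case in
  which Wilks' theorem fails; their null type-I error under the χ²₁
  reference measures ~22% at nominal 5% in simulation, against 5.2% for
  both-groups-observed features. Testing them by default would push the
  realised FDR of the BH procedure above its target, so they are excluded
  unless `single_group_features=True` is passed, which applies the
  boundary-supremum convention and accepts the liberal calibration.

## Simulator

The generator emulates a two-group label-free experiment: feature means
uniform on [5, 12] log2 units, i.i.d. normal replicate noise (SD 0.3 by
default, matching technical-replicate variability of peptide-level data),
a chosen number of two-fold DE features split evenly up/down with the fold
change applied symmetrically (±½ log2-FC per group, keeping the grand mean
at the drawn feature mean), and logit-linear missingness with defaults
(β0, β1) = (−6.0, 0.8), which yields ~37% missing values overall. One RNG
stream drives means → DE selection → noise → detection, so a dataset is
bit-reproducible from its seed. The defaults are the reference study
design used throughout the tests (10 000 features, two groups of 6).

What the simulator does *not* emulate: peptide-to-protein structure,
correlated or heavy-tailed noise, batch effects, per-sample detection
differences, or an imperfect (α < 1) detection asymptote (the capped model
is exercised with a purpose-built generator in its test). Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to real-data violations of it.

## Problem sizes and numerical conventions

The validation study uses 10 replicate datasets of 10 000 features for the
DPC-recovery and power summaries; the whole run completes in well under a
minute because every per-feature operation is vectorised. Ties in BH are
handled by the standard step-up minimum; NaN p-values are excluded from
adjustment and propagated. Matrix IO treats empty cells/`NA` as missing by
default, with an opt-in zero-as-missing dialect (MaxQuant convention) and
an optional raw-scale intensity floor, both applied before the optional
log2 transform; reading uses round-trip float parsing so write→read is
bit-exact.

## Known limitations

* The DPC is global; datasets with strong per-sample detection efficiency
  differences violate this and would need sample-level terms.
* σ² is plugged in, not profiled, in the LRT; p-values inherit mild
  liberal bias for features with very few observations (the BH target is
  still met in the reference simulation).
* The moderation hyperparameter estimator follows the canonical
  moment-matching construction; other choices (robust trimming,
  intensity-trended priors) would perturb results slightly.
* One-group-only features are excluded from the default test (see above);
  a principled reference distribution for that boundary case is open.
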