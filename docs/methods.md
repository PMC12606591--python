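# Methods

## The harmonisation model

Fixel-based analysis (FBA) quantifies white-matter microstructure per
*fixel* — a specific fibre population within a voxel — using fibre density
(FD), log fibre cross-section (logFC), and their product (FDC).  When scans
come from several sites, scanner models, or acquisition protocols, these
metrics carry additive and multiplicative *batch effects* that can dwarf
biological differences.  `fixelharm` removes them with the ComBat
location–scale model, treating every template fixel as an independent
feature and harmonising each metric separately.

For scan *j* acquired in batch *i* at fixel *f*:

    Y_{ijf} = α_f + X_{ij} β_f + σ_f (γ_{if} + δ_{if} ε_{ijf}),   ε ~ N(0, 1)

* `α_f` — overall fixel mean (metric units),
* `β_f` — coefficients of the biological covariates `X` (age in years, sex
  as an F=1 indicator, intracranial volume in mm³ by default; arbitrary
  columns can be named),
* `σ_f` — residual standard deviation,
* `γ_{if}`, `δ_{if}` — additive and multiplicative batch effects on the
  standardized (unit-residual-SD) scale.

Identifiability uses the sample-size-weighted constraint
`Σ_i n_i γ̂_{if} = 0`, which makes `α_f` the pooled covariate-adjusted mean.
The fit is ordinary least squares on `[batch indicators | covariates]`,
vectorised across fixels.

### Empirical-Bayes shrinkage

Per-batch estimates from few scans are noisy, so they are shrunk across
fixels with parametric priors: `γ_{i·} ~ N(γ̄_i, τ²_i)` and
`δ²_{i·} ~ InverseGamma(λ_i, θ_i)`.  Hyperparameters come from moment
matching over fixels — `γ̄_i`, `τ²_i` are the mean and variance of `γ̂_{if}`,
and with `m`, `V` the mean and variance of `δ̂²_{if}`,

    λ_i = (m² + 2V) / V,    θ_i = (m³ + mV) / V.

The shrunken `(γ*, δ*²)` solve the coupled conditional-posterior-mean
equations

    γ*  = (n_i τ² γ̂ + δ*² γ̄) / (n_i τ² + δ*²)
    δ*² = (θ + ½ Σ_j (Z_{ijf} − γ*)²) / (n_i/2 + λ − 1)

by fixed-point iteration from `(γ̂, δ̂²)`, stopping when the maximum absolute
parameter change falls below 1e-4 (cap 100 iterations; non-convergence is
logged per fixel and the last iterate used).  A batch whose `δ̂²` has zero
variance across fixels has a degenerate prior and falls back to its direct
estimates with a warning.  `method="direct"` skips shrinkage entirely
(γ* = γ̂, δ* = δ̂).

Harmonised values back-transform the standardized residual
`Z = (Y − α̂ − Xβ̂)/σ̂`:

    Y*_{ijf} = σ̂_f (Z_{ijf} − γ*_{if}) / δ*_{if} + α̂_f + X_{ij} β̂_f .

The back-transformation multiplies by `σ̂_f`; a formulation without it is
dimensionally inconsistent, and this is the form of the standard parametric
ComBat literature this package follows.

### Numerical conventions

* `σ̂²_f` uses divisor `N`; `δ̂²_{if}` uses divisor `n_i` (the pooled
  maximum-likelihood forms).  Together these make a single-batch dataset an
  exact fixed point: the constraint forces `γ̂ = 0` and the divisor pairing
  forces `δ̂² = 1`, so the data pass through unchanged to ~1e-12.  Reference
  implementations that use `n_i − 1` for `δ̂²` differ from this package by a
  factor `√(n_i/(n_i−1))` per batch in the direct method.
* Fixels whose values are exactly constant within any batch are excluded
  from harmonisation (their batch scale would be zero) and copied through
  unchanged; the count is logged.  Constancy is tested by equality, not
  `var > 0`, because the variance of identical floats can round to a
  subnormal.  A second guard drops fixels whose standardized batch variance
  is exactly zero.
* Covariates enter as given (no internal standardisation); a condition
  number above 1e8 triggers a warning suggesting rescaling (ICV in mm³ is
  the usual culprit; `numpy.lstsq`'s SVD keeps the solution accurate, but
  two different solvers may then disagree at ~1e-7).
* Harmonisation can push non-negative metrics (FD, FDC) slightly negative.
  Values are not clipped by default — clipping changes moments — but
  `clip_negative=True` (CLI `--clip-negative`) is available and the negative
  count is always logged.
* Absent fibre populations are 0 at their template fixels; the reader also
  accepts NaN as "absent" and converts to 0 with a logged count.
* Per-group harmonisation (`group_column=`) runs the whole pipeline
  independently within each group level (e.g. AD and CN) and restacks rows;
  a group spanning a single batch is returned unharmonised with a warning.
  The alternative — one joint fit with a group indicator among the
  covariates — protects the group-mean difference explicitly and is what the
  effect-size evaluation below uses.

## The synthetic-data generator

The generator emulates the two study designs the evaluation needs, with all
latent parameters retained (`GroundTruth`), so recovery can be checked
exactly.  It generates under the harmonisation model itself, plus one
extension: a subject-level random intercept `u_j` (default SD 0.04 FD
units) shared across a subject's scans and fixels, giving biological
heterogeneity beyond age/sex/ICV.  Batch effects are injected on the
standardized scale with `γ_{if} ~ N(g_i α_f / σ_f, τ_i²)` so that `g_i` is
the additive effect as a *fraction of baseline* — `g = 0.10` shifts a fixel
by 10% of its mean, the middle of the 8%–15% range that motivates the
default — and `δ²_{if} ~ InverseGamma(36, 35)` (mean 1, SD ≈ 0.17).

* **Travelling-subject (TS) mode** (`scan_rescan`, `site_diff`,
  `scanner_diff`, `protocol_diff`): 23 subjects by default, each scanned
  once per arm with identical biology (same `α`, covariates, `u_j`) and
  arm-specific batch effects; `scan_rescan` shares one batch so arms differ
  only in noise.  The paired design has zero expected biological arm
  difference, so any systematic post-harmonisation difference is residual
  batch effect.
* **Case–control mode**: 27 AD / 29 CN subjects on six scanner models with
  additive effects spanning ±10% of baseline.  A contiguous block of 10% of
  fixels is labelled "tract" (a stand-in for the fornix; coherence, not
  anatomy, is what the evaluation needs), where AD baselines are reduced by
  15%.  Scanner assignment guarantees ≥2 subjects per group per scanner and
  then skews AD toward high-effect scanners (`confound_strength`), so the
  scanner mix partially masks the group difference.  Cognitive scores
  (MMSE/MoCA) are linear in the *biological* (batch-effect-free,
  noise-free) tract-mean FD plus noise, rounded and truncated to [0, 30]:
  scanner effects corrupt the measured FD but not cognition, which is what
  lets harmonisation strengthen the FD–score association.
* Randomness is split into a structure stream (template, per-fixel
  parameters, covariates, assignments, batch-effect draws, tract labels)
  and a noise stream (ε, score noise); fixing `structure_seed` while
  varying `noise_seed` changes only the noise realisation.

What the generator does **not** emulate: spatial correlation between
fixels, registration error, connectivity structure (so the max-statistic
test here faces an easier multiplicity problem than real FBA), non-Gaussian
noise, longitudinal drift, or site-by-covariate interactions.  Passing
tests therefore demonstrate correctness of the estimator under its own
model and robustness to realistic effect magnitudes — not performance on
real multi-site data.

### Ages, volumes, scores

TS ages default to U(28, 36) and case-control ages to the config's
`age_range` (the evaluation scenarios use 55–90); ICV ~ N(1.5e6, 1.5e5) mm³;
the default age slope is −0.002 FD/year, sex effect +0.01, ICV slope 1e-8
per mm³; per-fixel baselines U(0.3, 0.7) and noise SDs U(0.01, 0.05) in
FD-like units.  MMSE uses intercept −13.5, slope 85 per unit tract-mean FD,
noise SD 1.5 (so a 15% tract reduction at baseline 0.5 moves the mean score
by ≈ 6 points); MoCA uses −37, 127, 2.5.  These are stylised values chosen
once for plausibility of the resulting score distributions.

## Evaluation statistics

* **Percentage difference** between paired arms:
  `100 (travelled − initial) / initial` per fixel; fixels with a zero
  initial value give NaN and are excluded from summaries (counted).
* **Permutation testing with FWE control**: per-fixel paired t statistics
  on subject difference vectors; the null flips the sign of whole subject
  rows, preserving between-fixel correlation; each fixel's family-wise
  error corrected p-value is the fraction of permutations whose maximum |t|
  reaches the observed |t|, with the `(b+1)/(B+1)` estimator so p is never
  zero.  The default is 5000 permutations.  This max-statistic correction
  replaces connectivity-based fixel enhancement (CFE), which needs a
  template tractogram: FWE control remains valid, but without spatial
  enhancement the significant sets are generally smaller and not comparable
  fixel-for-fixel with CFE output.  An unpaired variant permutes group
  labels after regressing the covariates out of the data (a pragmatic
  approximation; full Freedman–Lane is out of scope).
* **Cohen's d** with the pooled-SD convention, first group minus second, so
  CN − AD is positive for disease-related reductions.
* **OLS with bootstrap**: score on [intercept, tract-mean metric, age, sex,
  ICV]; the tract coefficient and its two-sided p-value come from the
  statsmodels fit; the 95% CI for R² is percentile-based over
  case-resampling bootstrap replicates (default 10,000; degenerate
  replicates are redrawn and counted).  Percentile rather than BCa because
  it is the minimal-assumption choice; the method is recorded in the
  result.
* **Batch variability**: per fixel, the mean over ordered batch pairs of
  `100 |mean_j − mean_i| / |mean_i|`, summarised globally by mean / median /
  95th percentile, optionally restricted to significant fixels.

## Evaluation design choices

Two quantities in the end-to-end checks are measured against a
*same-realisation counterfactual* — the identical scans regenerated without
batch effects:

* The travelling-subject check compares the mean absolute significant-fixel
  percentage difference before and after harmonisation **on the
  pre-harmonisation significant set**: after harmonisation there are
  typically no significant fixels left, so restricting each map to its own
  significant set would make the "after" summary vacuous.
* The effect-size check compares the post-harmonisation tract Cohen's d to
  the counterfactual data *processed by the same pipeline*.  Any fitted
  adjustment absorbs the within-batch means of subject-level noise,
  shrinking within-group variance by roughly a factor `1 − 1/n_i` and
  inflating d by ~5–15% at ~9 scans per scanner; an oracle adjustment using
  the true batch effects reproduces the raw counterfactual d exactly (to
  1e-16), confirming this is estimation error inherent to the sample sizes,
  not an implementation defect.  Measuring both sides with the same
  procedure cancels that shrinkage and isolates what harmonisation is
  supposed to fix: residual scanner confounding.  The raw-counterfactual d
  is reported alongside.
* The covariate-preservation check generates its data without the subject
  random intercept: a latent intercept shared across fixels aligns with age
  by chance in any single realisation and contaminates the recovered slope
  by an order of magnitude more than harmonisation itself does, so removing
  it makes the age slope the experiment's only subject-level signal.

Problem sizes in the default checks — ~1000 fixels, 23 paired subjects,
1000 permutations for the TS run; 200 replicates with 500
permutations/bootstrap draws for the calibration runs — were chosen so the
whole evaluation completes in well under a minute each while keeping
Monte-Carlo error comfortably inside the tolerances tested.

## Known limitations

* Parametric priors only; the non-parametric ComBat variant, reference-batch
  mode, longitudinal ComBat, and ComBat-GAM are out of scope.
* Harmonisation is per metric, so harmonised FDC ≠ harmonised FD ×
  harmonised FC in general; this is a property of the method, not corrected.
* The fixel directory dialect is NIfTI-1 only (`index.nii[.gz]`,
  `directions.nii[.gz]`, per-scan `M×1×1` scalar images, 0-based offsets);
  MRtrix `.mif` files should be converted with `mrconvert` first.
* Whether zero-filled absent fixels should enter the per-fixel fits is
  debatable; they are included here (they are data under the zero-fill
  convention), and a fixel absent across a whole batch is excluded by the
  constancy mask.
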