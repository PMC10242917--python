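# Methods

## The problem

In imputation-based GWAS the genotype `G ∈ {0, 1, 2}` of sample *i* at a
variant is not observed; imputation software reports a posterior triplet
`(p0, p1, p2)`, the dosage `D = p1 + 2 p2`, the best-guess genotype
`W = argmax_k p_k`, and a quality score Rsq. This package implements and
compares four single-variant association tests that consume these quantities,
and a simulator that generates them with controlled MAF and imputation
quality.

## The four tests

**Dosage.** OLS (quantitative, Wald t with n−2 df) or maximum-likelihood
logistic regression (binary, Wald z) of the phenotype on `D`. The standard
errors treat `D` as known; uncertainty enters only through the attenuation of
`D` towards its mean.

**Unconditional MI.** M independent completed datasets are created by drawing
`G̃ ~ Categorical(p0, p1, p2)` per sample, each is fitted by the same GLM, and
the estimates are pooled by Rubin's rules: `q̄ = mean(β̂_m)`,
`W̄ = mean(se²_m)`, `B = var(β̂_m)` (ddof 1), `T = W̄ + (1 + 1/M) B`, with a
t reference on `df = (M−1)(1 + W̄/((1+1/M)B))²` (normal when `B = 0`). The
draws ignore the outcome, so this is "improper" imputation: the imputed
genotype–outcome correlation is biased towards zero while `T` still adds the
between-imputation variance, making the test conservative. Draws that produce
a monomorphic genotype vector or a non-converging logistic fit (perfect
separation is common at MAF ~ 0.001) are dropped and `m_used` records the
survivors; below 2 the result is flagged non-converged rather than invented.

**MRM.** The marginal likelihood of the phenotype is the three-component
mixture `f(y_i) = Σ_k p_ik f(y_i | G = k; β0, β1[, σ²])` with Gaussian
(quantitative) or Bernoulli-logistic (binary) components; association is the
1-df LRT of β1 = 0. Under the null the mixture collapses (all components
identical), so the null maximum likelihood is closed-form. The alternative is
maximised by BFGS with analytic gradients in responsibility form; σ² is
optimised on the log scale; starting values come from the dosage regression;
up to three jittered restarts are attempted. The gradient tolerance scales
with n (`max(1e-8, 1e-9·n)`) because the log-likelihood and its numerical
noise floor grow linearly in the sample size; a restart whose final gradient
is within 100× this tolerance is accepted as converged. The reported standard
error is from the numerically differentiated observed information; the test
itself is the LRT.

**MI SMCFCS.** Imputation is recast as classical measurement error: `D` and
`W` are modelled as two replicates `G + noise` with shared error variance
`var_u`, and the latent `G` as Normal(`mu_x`, `var_x`) (free moments, not
HWE-constrained). Each of M independent chains runs a fixed number of cycles
(default 10); one cycle:

1. fit the substantive model `y ~ G` on the current imputation and draw θ*
   from the asymptotic normal approximation of its posterior (for
   quantitative traits the residual variance is drawn scaled-inverse-χ²
   style, `RSS/χ²_{n−2}`);
2. update the measurement model — `var_u` from the within-sample dispersion
   of `(D, W)` around the imputed `G` (drawn `2n·v̂/χ²_{2n}`, floored at
   1e-8 so that `D = W` exactly degenerates gracefully), `mu_x`/`var_x` from
   the imputation's moments with matching approximate-posterior draws;
3. per sample, propose `G^C` from the measurement-only conditional
   Normal — precision `1/var_x + 2/var_u`, mean the precision-weighted blend
   of `mu_x`, `D` and `W` — and accept with probability
   `f(y | G^C, θ*) / sup_G f(y | G, θ*)` (exp(−resid²/2σ²) for Gaussian,
   the Bernoulli likelihood itself for logistic). Attempts are drawn in
   geometrically growing vectorised batches up to a cap (default 1000);
   samples that never accept keep the highest-likelihood proposal seen.

The final cycle's continuous `G` (never rounded to allele counts) is one
completed dataset; the substantive fits over the M chains are pooled by
Rubin's rules. Because the acceptance step conditions on the outcome, the
imputation is compatible with the analysis model, which restores calibration
and corrects regression-dilution bias (verified directly: data generated
under the replicate model with slope 0.5 and error sd 0.3 are recovered with
relative bias below 10% at n = 5,000). `D` and `W` are treated as
conditionally independent replicates although they derive from the same
posterior; this misspecification is accepted as-is and the procedure is
empirically robust to it.

## The simulator

True genotypes are i.i.d. Hardy–Weinberg draws at the variant's MAF.
Imputation error is a one-parameter Gaussian-signal model: a latent signal
`s = g + Normal(0, ν²)` is observed and the reported posterior is the exact
Bayes posterior over {0, 1, 2} combining the HWE prior with the Gaussian
likelihood. This yields `D = E[G | s]`, so the posteriors are perfectly
calibrated, dosage variance obeys `Var(D) = Rsq · Var(G)`, and the achieved
true Rsq (`cor²(D, G)`) decreases monotonically in ν — a single dial,
calibrated by bisection with common random numbers (`calibrate_noise`;
default Monte-Carlo size 50,000). Experiment drivers cache the calibration on
a log-MAF × Rsq grid (`NoiseCalibrator`, bilinear interpolation, accurate to
about ±0.02 in Rsq).

Defaults that define the study conditions:

* MAF within a bin: log-uniform (mimicking the skew of real site-frequency
  spectra towards the bin's lower edge); uniform available by config.
* Target Rsq within a bin: uniform on `[low, min(high, 0.97)]`; the 0.97 cap
  avoids an atom at exactly 1 in the top bin (a degenerate range at 1 still
  yields perfect posteriors).
* Estimated Rsq: the MaCH/minimac convention `Var(D) / (2 p̂ (1 − p̂))` with
  `p̂ = mean(D)/2`.
* Concordance filter: a simulated variant enters an experiment only if
  `|Rsq_est − Rsq_true| / Rsq_true < 0.2`, strict inequality.
* Phenotypes: quantitative `y = β1 g + N(0, 1)`; binary
  `P(y=1|g) = expit(β0 + β1 g)` with `β0 = log(τ/(1−τ))` for prevalence τ;
  null phenotypes are N(0,1) or Bernoulli(τ) independent of everything.
* Power studies: each variant gets its own effect size from |N(0,1)|,
  restricted to the cell's odds-ratio interval via the inverse half-normal
  CDF (`β = log OR` for binary traits; quantitative cells use the same
  log-scale cut-points for β directly); significance α = 5×10⁻⁸.
* All randomness flows through a `SeedSequence` hierarchy
  (experiment seed → bin → variant → method), so any single variant is
  re-simulatable in isolation and deterministic methods replay bit-for-bit.

### What the simulator does and does not emulate

It reproduces the *marginal* statistical structure that drives the method
comparison: HWE genotype frequencies, a tunable dosage–truth correlation, and
posterior triplets whose asymmetry grows as MAF falls. It does **not**
reproduce linkage disequilibrium (one variant at a time), haplotype-level
imputation artefacts, or — importantly — any *miscalibration* of real
posteriors. Because the synthetic posteriors are exact Bayes posteriors, the
law of total variance pins the mean posterior variance at
`(1 − Rsq)·Var(G)`; real pipelines' posteriors can be effectively more
confident at the same true Rsq. Consequences: null-calibration and power
*patterns* (which methods are calibrated, which are conservative, how power
orders) transfer, but the *magnitude* of unconditional-MI conservativeness
in a given Rsq bin does not. A back-of-envelope for the null z² deflation of
unconditional MI with calibrated posteriors,
`(R + (1−R)/M) / (1 + (1+1/M)(1−R))`, gives 0.46–0.68 across Rsq 0.6–0.8
(M = 5), and the simulated GC lambda in that bin lands around 0.5–0.6 — whereas the
cohort-scale reference value for the same bin is 0.726, implying an effective
R ≈ 0.84 for the real posteriors. Passing tests therefore demonstrate the
mechanism and the qualitative findings, not bin-level numerical equality for
this quantity.

## Numerical choices

* GLM backend: closed-form OLS and a 2-parameter Fisher-scoring logistic
  solver (score tolerance 1e-10, 30 iterations, η clipped at ±30); perfect
  separation or |β1| > 15 is flagged non-converged with NaN p rather than
  raised. Agreement with statsmodels is enforced in the test suite.
* Rubin pooling snaps `B` to zero when it is below 1e-14 of the estimate
  scale (numerically identical imputations).
* GC lambda: `median(χ²)/0.4549` with p-values converted through the 1-df
  χ² quantile; p = 0 is clipped to the smallest positive float with a
  warning; at least 20 p-values are required. The Monte-Carlo standard error
  `1/(2 f(m) √N) / 0.4549` is reported beside every lambda (≈ 0.107 at
  N = 500 — per-bin lambdas at desk scale carry real sampling noise).
* QQ points use the `(i − 0.5)/n` uniform order-statistic convention.
* Empty bins (nothing survives the concordance filter) raise rather than
  emit NaN.
* VCF text precision: GP/DS written with 4 decimals; on read, GP rows with
  sums in [0.98, 1.02] are renormalised, anything worse is an error;
  multi-allelic sites are skipped with a warning; per-sample missing GP
  drops the sample for that variant.

## Desk-scale problem sizes

The bundled studies are scaled to a single workstation: null-calibration runs
use 250–500 variants per MAF × Rsq bin at n = 20,000 (the per-bin lambda MC
error is then 0.10–0.15), power cells use 100–200 variants at n = 50,000, and
the acceptance script uses 300 variants for the power cell and 1,000 for the
lambda bin. Cohort-scale runs (tens of thousands of variants per bin) are a
matter of raising `n_variants`; everything is embarrassingly parallel across
variants.

## Known limitations

* Single-variant, biallelic, covariate-free tests (residualize first);
  quantitative-trait effect-size bins are a documented convention, not a
  reproduction of any published table.
* The MRM standard error (observed information) is reported for completeness;
  inference is by the LRT.
* The SMCFCS latent-genotype model is Gaussian with free moments; at very low
  MAF the Gaussian approximation of a {0,1,2} variable is crude, yet the
  pooled test remains empirically calibrated in the bins studied here.
* Unconditional MI's conservativeness magnitude depends on posterior
  calibration (see above): compare like with like before quoting lambdas.
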