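# Methods

This note documents the statistical machinery, the synthetic-data model
behind every test, the numerical choices, and the limits of what passing
tests demonstrate.

## GCA factor construction

The ten-test battery is summarized by an exploratory bifactor pipeline:

1. **ML factor extraction.** Four-factor maximum-likelihood EFA of the
   train correlation matrix, via the Lawley profile likelihood over the
   uniquenesses ψ (eigendecomposition of Ψ^{-1/2}RΨ^{-1/2}). The bounded
   10-parameter problem is solved by an in-module projected BFGS with
   analytic gradients (ψ bounded in [0.005, 1], matching common practice);
   scipy's L-BFGS-B is the fallback when the primary search does not reach
   tolerance. Solutions agree with base-R `factanal` to ~1e-3.
2. **Oblimin rotation.** Quartimin (oblimin γ = 0) via Jennrich's oblique
   gradient-projection algorithm. Cold fits use the identity start plus six
   deterministic random starts, keeping the lowest criterion — the
   quartimin surface has genuine local minima for highly symmetric loading
   patterns. Refits inside cross-validation and permutation loops warm-start
   from the previous rotation.
3. **Second order + Schmid–Leiman.** A one-factor ML EFA of the 4×4 factor
   correlation matrix gives second-order loadings γ_k; the Schmid–Leiman
   split is Λ_g = Λ₁γ and Λ_f = Λ₁·diag(√(1−γ²)).
4. **Scoring.** Regression (Thurstone) weights W = R⁻¹Λ_g applied to
   test scores standardized with *train* means and SDs. Whether the
   original workflow standardized test subjects with train or test
   statistics is not documented; train statistics are the only
   leakage-free choice inside cross-validation, so they are used
   throughout.

ω_h uses the standard sum-score decomposition (README formula); SRMR is the
root-mean-square of the off-diagonal lower-triangle residual correlations.
Comparative fit indices (CFI/RMSEA/BIC) would require full SEM machinery
and are not implemented. ICC(2,1) is computed from the explicit two-way
ANOVA decomposition; it matches `pingouin.intraclass_corr`'s ICC(A,1).

Known degeneracies, flagged rather than hidden: forcing four group factors
onto data with little group variance produces spurious singleton factors at
the ψ boundary (Heywood cases; warned and flagged on the model object), and
on exactly one-factor population matrices the higher-order decomposition is
unidentified.

For the repeated refits inside permutation loops, all fold × permutation
factor problems are solved in one batched pass (stacked eigendecompositions,
a projected Barzilai–Borwein descent for ψ, vectorized quartimin).
Unconverged problems fall back to the sequential path; batched and
sequential solutions agree to ~1e-4 in the scoring weights.

## BBS model

PCA centers voxels on train means and does not variance-scale (the
convention of the reference implementation of the method); the SVD route is
used for numerical stability at m ≫ n. K defaults to 75 and is clipped to
n_train − 1 with a warning. Component signs are fixed (largest-|loading|
voxel positive) so results are reproducible across BLAS implementations.
The joint regression y = Xβ + Zγ + ε is solved by minimum-norm least
squares, which makes the K = n−1 case well-defined and exactly equivalent
to minimum-norm regression on the centered voxel matrix (a tested
invariant). The intercept lives in Z; continuous covariates are z-scored on
train, categorical covariates dummy-coded, and mean framewise displacement
is task-specific. Consensus maps are the β-weighted component sums,
z-scored over voxels.

## Cross-validation and inference

Families never straddle folds: families are shuffled by seed and assigned
greedily to the smallest fold, bounding fold-size imbalance by the largest
family size. Everything estimated — factor model, basis, covariate scaling,
regression — is refit per fold on train data only; a "poisoned test set"
test asserts that corrupting held-out subjects changes no trained
coefficient.

Pooling: Fisher r-to-z average for correlations; arithmetic means for
R²_cv and MSE. The fold interval is mean ± 1.96·SD of per-fold r; the
source text's "mean and SD" is taken literally (SD, not SEM), switchable
via `use_sem`. In R²_cv the reference mean ȳ_train is the covariate-
*adjusted* train mean (near zero since Z contains an intercept), which
makes ỹ and ȳ commensurable.

Freedman–Lane permutation operates on the ten raw test-score rows: the
nuisance-only model S = Zγ + E is fit once per iteration set on the full
sample, residual rows are permuted (one shared permutation across tests,
preserving the battery's internal structure), scores are reconstructed, and
the complete cross-validation — including per-fold bifactor refits — is
rerun. Residualization happens once on the full sample rather than per
fold, because the permuted unit must be exchangeable across the whole
sample. Permutations ignore family structure by default (exchangeability
assumed); `within_family=True` restricts shuffles to within families as a
documented extension. The p-value is the rank of the observed pooled r in
the null divided by B, reported as 1/B (with an `exceeds_all` flag) when
the observed value beats every draw — the literal rank/B rule, not the
(rank+1)/(B+1) correction, matching the described procedure. With B = 99
the achievable p floor is ≈ 0.0101.

## Intrinsic dimensionality

The Levina–Bickel ML estimator with the recommended k ∈ [10, 20] (the
source analysis names no range), point-averaged per the original scheme;
the inverse-averaging (MacKay–Ghahramani) correction is available via
`average_inverses`. Exact brute-force neighbor search — n here is at most a
few thousand.

## Connectome comparator

Framewise displacement follows the Power convention (sum of absolute
translation deltas plus 50 mm × absolute rotation deltas), since only the
0.5 mm threshold, not the formula, is stated in the source description.
Subjects with strictly more than 25% of frames above 0.5 mm are excluded.
Processing order: linear detrend + CompCor-style regression of the top five
principal components of caller-supplied noise-tissue signals (tissue
segmentation is out of scope, so white-matter/CSF surrogates are an input),
4th-order zero-phase Butterworth band-pass 0.01–0.1 Hz, then scrubbing —
censored frames are simply dropped before correlation, with no
interpolation. Features are Fisher-z ROI-pair correlations, upper triangle
in fixed row-major order, feeding the identical BBS/CV machinery.

## Synthetic-data model

The generator encodes the study conditions all tests run under.

* **Cohort.** Default n = 967 subjects in families drawn from sizes 1–5
  with probabilities (0.45, 0.35, 0.12, 0.06, 0.02) — the real family-size
  distribution is not public, so these are plausible twin-cohort
  proportions. Latent g = √icc·(family effect) + √(1−icc)·(individual),
  family_icc = 0.4, tilted by a motion confound (strength 0.2) so that
  high-motion subjects have slightly lower g and motion-contaminated maps —
  exercising the covariate adjustment.
* **Behavior.** Test j = λ_gj·g + Σ_f λ_fj·f + √ψ_j·e with general
  loadings 0.7 and group loadings 0.4 in blocks (2, 3, 3, 2); unit
  population variance. A retest session targets a per-test retest
  correlation of 0.78. Note the GCA *composite* ICC(2,1) then lands near
  0.9: aggregating ten tests cancels unique noise, so composite reliability
  exceeds per-test reliability by construction.
* **Maps.** map_i = demand·amplitude·(1_FPN − 1_DMN) + Σ_k s_ik·C_k +
  confound·FD_z·C_motion + white noise (SD 0.5). The C_k are unit-norm,
  smooth (moving-average within the 1-D voxel ordering), network-localized
  patterns fixed by seed; expression-score SDs (4, 3, 2.5, 2, 1.5) put the
  components above the Marchenko–Pastur noise edge so PCA can find them.
  The first component's score is g-coupled in proportion to the contrast's
  demand, s_i1 ∝ (coupling·demand·g_i + η_i), so the prediction ceiling for
  a contrast is cd/√(c²d²+1). The default coupling 0.7 at demand 1 puts
  the best contrast's cross-validated accuracy in the high-0.4s, the
  regime the method is known to operate in. Demand levels for the 15
  default contrasts grade from 1.0 (working-memory 2-back−0-back) down to
  ~0.1 (motor, reward−punish difference contrasts).
* **ROI time series.** A low-rank (10-factor) model whose first factor's
  variance scales with g (coupling 0.35 × gca_coupling, chosen so the
  resting-state comparator carries a real but clearly weaker signal than a
  demanding task contrast); motion traces are slow random walks with
  seeded ~4% spike frames that exceed the 0.5 mm FD threshold.

What the generator does **not** emulate: 3-D spatial geometry (maps are
vectors with 1-D smoothness — sufficient because every downstream
computation is geometry-blind), spatially autocorrelated noise (map noise
is white, so Levina–Bickel estimates on synthetic matrices reflect the
white-noise floor, not the ~70-dimensional structure of real smooth data),
hemodynamics and task timing, and non-Gaussian score distributions.
Passing tests therefore demonstrate correctness of the *machinery* and
calibration of its inference, not the real-data effect sizes.

## Problem sizes and determinism

Test-suite simulations are scaled to single-CPU minutes: the permutation
calibration check uses 200 replicate null cohorts of n = 300 with 400
voxels and B = 99; signal recovery compares an n = 800 cohort against a
20,000-subject large-sample oracle at 1,000 voxels; the demand analysis
suite uses n = 150 with 400 voxels over 10 seeds. The acceptance script
uses n = 400 with the full 2,000 voxels and B = 99. All randomness flows
through explicit seeds (study runs derive stage-specific substreams from
one base seed), and reports are byte-identical across reruns with the same
configuration.
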