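# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `caprigen`.

## The animal model and REML

The core model is the multi-trait GBLUP animal model

    y = Xb + Zg + e,    g ~ N(0, G ⊗ M),    e ~ N(0, I ⊗ R)

where y stacks t trait vectors, X carries the fixed effects (explicit
intercept plus treatment-coded milk-production status and birth year, the
first level of each factor as reference), G is the genomic relationship
matrix, and M and R are the t×t genetic and residual covariance matrices.
Heritability is h² = M_kk/(M_kk + R_kk); the genetic correlation between
traits k and l is M_kl/√(M_kk M_ll).

**Estimation.** REML works in the eigenbasis of G. With G = U D Uᵀ, the
rotated records ỹ = Uᵀy are independent across individuals with
per-individual covariance Vᵢ = dᵢM + R, so one restricted-likelihood
evaluation costs O(n t³) after a single n×n eigendecomposition. (M, R)
are parameterized by their Cholesky factors, which keeps every iterate in
the PSD cone — the same square-root device commonly used to constrain
covariance estimates — and the restricted log-likelihood is maximized with
L-BFGS-B (max 500 iterations, function tolerance 1e-9 relative, gradient
tolerance 1e-7; non-convergence is flagged on the result, never silent).
Starting values split the OLS-residual covariance equally between M and R.
This direct maximization replaces the EM/average-information iteration
used by classic variance-component programs: with the eigenbasis trick the
likelihood is cheap enough that a quasi-Newton optimizer on the Cholesky
scale is simpler and at least as robust (no PSD-cone step rejection logic).

**G and blending.** G = MM′/Σ2pⱼqⱼ with M the column-centered dosage
matrix, pⱼ = (mean dosage)/2 computed on non-missing calls, and missing
dosages imputed to 2pⱼ (centered zero) so the denominator is consistent
across entries. Centering makes G·1 = 0, so a raw G always has one zero
eigenvalue. Two consequences:

- REML never inverts G (only Vᵢ, which stays PD through R), so variance
  components are estimated on the **raw** G. Blending w·G + (1−w)·I would
  scale the off-diagonal genetic covariances by w and inflate ĥ² by about
  1/w — a 1.5–2 point bias at w = 0.95 — so it is deliberately not applied
  in the estimation path.
- The mixed-model equations do invert G, so every prediction path uses the
  blended 0.95·G + 0.05·I (weight exposed as a parameter). 0.95 mirrors
  the convention of standard genetic-evaluation suites; after blending the
  smallest eigenvalue is at least 0.05.

**GBLUP prediction.** Henderson's MME are solved with all genotyped animals
as random effects and only training records in y; animals without records
receive predictions through their genomic relationships, identically to
the projection ĝ_test = G_test,train G_train,train⁻¹ ĝ_train (both routes
are implemented and tested to agree). Cross-validated prediction is
single-trait per trait; the multi-trait model serves parameter estimation.

## Machine-learning predictors

Both consume **relationship features**: the feature vector of an animal is
its row of G restricted to the training animals (column order fixed by the
training-id order). This keeps dimension at n_train and makes the linear
special case exactly comparable to GBLUP — KRR with the precomputed kernel
K = G_train and ridge λ = σ²e/σ²g reproduces GBLUP training breeding
values, a tested equivalence.

**KRR.** Solves (K + λI)c = y; prediction f(x) = k(x, X_train)·c. The ridge
parameter is fixed at α = 1.0 (exposed as a flag). The kernel is chosen per
training split by an inner 5-fold grid search maximizing mean prediction
correlation over a default grid of linear, three RBF bandwidths around the
1/d heuristic, and a quadratic polynomial kernel; ties resolve to the
earliest grid entry.

**Adaboost.RT.** D₁(i) = 1/n; each round fits the weak learner on a
D_t-weighted bootstrap resample (repeated rows are collapsed into integer
sample weights, which fits the identical CART tree at lower cost), computes
absolute relative errors ARE, sets ε_t = Σ_{ARE>φ} D_t(i) (clamped to
(1e-10, 1−1e-10) to keep committee weights finite), multiplies the weights
of correctly predicted samples by ε_t exactly as the update rule is
printed — not the ε_tⁿ power of the original Adaboost.RT publication — and
renormalizes. The committee is the log(1/ε_t)-weighted mean of the weak
learners, hence always a convex combination of their outputs.

Design choices that the source protocol leaves open, fixed here once:

- φ = 0.1 by default (small relative-error thresholds are conventional;
  exposed as a flag). With near-centered targets most rounds have ε_t near
  1, so the committee behaves close to bagging; larger φ sharpens the
  reweighting.
- The ARE denominator is floored at max(|y_i|, 0.1·SD(y)) because the
  regression targets are fixed-effect-adjusted (near-centered) phenotypes,
  for which a raw relative error is ill-posed around zero.
- The weak learner is a depth-3 regression tree; a stub-learner injection
  point exists so the update arithmetic can be unit-tested exactly.

## Synthetic data

The generator emulates the statistical structure of a dairy-goat udder
evaluation: defaults are 635 individuals, three traits with genetic
variances {4.23, 35.07, 1.40} cm², residual variances {22.21, 74.52, 9.37}
cm² (heritabilities 0.16/0.32/0.13), genetic correlations
{0.79, 0.70, 0.45}, residual covariances back-derived from phenotypic
correlations {0.72, 0.80, 0.51} (the implied residual correlation matrix
is PD), trait means {17.15, 29.65, 11.96} cm, 82% of animals in milk and
three birth-year groups. The marker panel defaults to 5,000 independent
HWE SNPs with MAF uniform on [0.05, 0.5] — a desk-scale stand-in for a
sequence-level panel — with 500 causal markers.

Mechanics: allele frequencies are drawn per marker, dosages as two
Bernoulli gametes (HWE), missingness uniformly at a configurable rate.
Breeding values are built from causal markers with multivariate-normal
effects and then linearly recolored so the **realized** genetic covariance
equals M exactly (the recoloring acts on the effect vectors, so breeding
values remain linear functions of causal dosages). Epistasis, when
requested, moves a fraction of the genetic variance into centered pairwise
products of randomly paired causal loci, each component recolored to its
variance share; the additive/epistatic cross-covariance is zero in
expectation under HWE. Fixed-effect magnitudes are not identified by any
published summary; defaults are modest (0.25 phenotypic SD) and
user-settable. Recorded true breeding values are the total genetic value.

**What the generator does not emulate:** family/pedigree structure,
linkage disequilibrium, and selection. All individuals are unrelated, so
off-diagonal relationships are pure noise of order 1/√m. Two consequences
for interpreting the tests: (i) prediction accuracies at n = 600 and
m = 5,000 are intrinsically small (Daetwyler-type expectation ≈ 0.06–0.10
against adjusted phenotypes), and REML heritability estimates carry a
per-replicate SE near √(2m)/n ≈ 0.17 — parameter-recovery checks therefore
average ≥ 20 replicates; (ii) tree-based committees, which on real data
can exploit blocks of high relationship values, have nothing to split on
when relationship features are unstructured noise. In benchmark runs at
n = 600, m = 5,000 (10 seeds, 10-fold CV, udder-depth architecture) the
measured mean accuracies are GBLUP +0.069 / KRR +0.069 / Adaboost.RT
−0.022 with 30% epistatic variance, and the Adaboost.RT deficit persists
(−0.11 vs GBLUP) under a purely additive architecture; reference AdaBoost
regressors on the same features behave the same, and the deficit remains
even at h² = 0.8 on a dense panel. The "non-linear methods win under
epistasis" comparison should therefore be expected to reproduce on data
with family structure, not under this generator; the corresponding
benchmark test is expected to fail for Adaboost.RT and is retained
unchanged as documentation of that fact. Passing tests demonstrate
correctness of the machinery and of the statistical contracts, not
real-data method rankings.

## Cross-validation protocol

Records are permuted once (seeded) and split into k = 10 near-equal folds.
Within each training split, fixed effects are re-estimated by OLS
(training-only, avoiding leakage into the adjusted validation targets),
GBLUP re-estimates variance components by REML, and KRR re-selects its
kernel. Validation animals whose factor level was unseen in training
receive the reference-level adjustment with a logged warning. Accuracy is
the Pearson correlation between predictions and adjusted phenotypes;
zero-variance folds yield NaN and are excluded from summaries with a
warning. Per-(method, trait) summaries report mean, across-fold SD and a
normal-approximation 95% CI (mean ± 1.96·SD/√k). Method improvements are
rounded to integer percent of the baseline. A single fixed phenotype
realization can chance-align with eigenvectors of G and show spurious
within-realization "signal" in every fold; null-behavior checks therefore
average over independent phenotype draws.

## Problem sizes used in the test suite

Unit tests run on populations of 200–500 individuals and 100–5,000
markers. Parameter-recovery checks use 20 replicates at n = 600,
m = 5,000; the cross-validated method comparison uses 10 seeds per
architecture at the same size. These sizes were chosen so the full suite
completes in well under half an hour on one CPU while keeping Monte-Carlo
error below the stated tolerances.

## Known limitations

- No pedigree, LD, dominance or selection in the generator; no single-step
  (H-matrix) evaluation.
- Standard errors of variance components are not reported (the information
  matrix of the transformed parameterization is not propagated).
- The HWE QC rule is interpreted as |observed − expected heterozygote
  frequency| > 0.15 — the only dimensionally coherent reading of a 0.15
  cutoff without a named test statistic.
- The genetic-correlation formula uses the standard definition
  σ_g12/√(σ²_g1 σ²_g2).
- VCF input is biallelic-GT only; multi-allelic records are skipped with a
  count.
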