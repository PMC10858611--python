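# Methods

This note documents the statistical model behind `rfqt`, the defaults and
why they are set as they are, the numerical choices, and what the built-in
simulation evidence does and does not establish.

## Setting and estimand

The data are one sample of n individuals with an instrument Z (a genetic
variant dosage or a weighted allele score, built by
`weighted_score(dosages, weights)`), a continuous exposure X, a continuous
outcome Y, and p candidate covariates M₁…M_p. The target of a stratified
analysis is the conditional average treatment effect — the causal effect of
the exposure at given covariate levels. The package does not assume the
covariates are the true effect modifiers: heterogeneity between
stratum-specific instrumental-variable estimates may reflect effect
modification, mediation, non-linearity, or correlation with unmeasured
modifiers. The estimates are still informative about *who* would respond
differently to intervention on the exposure.

All estimation assumes Z is a valid instrument in the full sample
(relevance, exchangeability, exclusion restriction), linearity and
homogeneity of the instrument–exposure and instrument–outcome associations
*within* strata, and complete-case data (rows with missing values are
dropped at load; no imputation).

## Stratification

Three stratifiers share a common contract: per-individual labels 1..K with
realized sizes matching target proportions by largest-remainder rounding,
and all rank ties broken at random from one seeded RNG stream per call.

- **naive** — contiguous covariate-rank blocks. Biased whenever the
  covariate is a function of the instrument (collider).
- **residual** — naive applied to the OLS residual of M on Z. Valid under
  M = M(0) + αZ with constant α.
- **doubly-ranked** — rank by Z, form consecutive pre-strata of size 10
  (configurable; the trailing pre-stratum keeps its smaller size and is cut
  by the same proportions), rank by M within pre-strata, and take equal
  covariate-rank slices from each pre-stratum. Valid under the weaker
  rank-preserving assumption: each individual's counterfactual covariate
  values keep the same rank across instrument values. Because every
  pre-stratum contributes equally to every stratum, the instrument
  distribution is balanced across strata by construction.

A pre-stratum size of 10 trades instrument homogeneity within pre-strata
against covariate-rank resolution; it is the conventional choice and is
exposed as a hyperparameter. Discrete covariates are accepted with a
warning — with few distinct values the within-pre-stratum ranking is mostly
tie-breaking noise.

## Stratum estimates and the Q statistic

Per stratum, β̂_Xk and β̂_Yk are intercept-including OLS slopes with
classical SEs; θ̂_k = β̂_Yk/β̂_Xk. Cochran's Q compares the strata to their
inverse-variance-weighted average θ̂, with weights 1/se_k² using the
first-order ratio SE se_k = σ_Yk/|β̂_Xk|, and denominator
σ²_Yk + θ̂²σ²_Xk evaluated at that fixed θ̂. A flag (`iterate_theta`)
instead minimizes Q over θ, the profile-likelihood variant; the default is
the fixed IVW value. Strata with fewer than 3 members or a constant
instrument are flagged, logged, and dropped from the IVW average and from Q
with the degrees of freedom reduced accordingly.

**A calibration caveat that matters.** The χ²_{K−1} reference for Q assumes
the numerator's variance equals σ²_Yk + θ̂²σ²_Xk. In a one-sample analysis
β̂_Xk and β̂_Yk are estimated from the same individuals and their errors are
correlated — strongly so when confounding is strong or the causal effect is
large, since both push the same error terms into X and Y. The omitted
−2θ̂·cov term then makes Q conservative. Under this package's own simulator
(20 shared confounders, effect 0.5) the null mean of a K=10 Q is ≈ 3.5
rather than 9, and the 5% χ²₉ test rejects essentially never; with
independent association errors of matched instrument strength the same code
gives null mean ≈ 9.0 and rejection ≈ 5–7% (per-stratum F ≈ 8). The
practical consequences: (i) the χ² p-value reported with Q is conservative
for one-sample data; (ii) tree growth, which compares Q to 3.84, splits
conservatively under the null; (iii) honest null calibration of forest-level
heterogeneity should use the permutation test, which is exact by
construction and is what the package recommends.

## Q trees

At each node, every candidate covariate × proportion in {3:7, 5:5, 7:3} is
evaluated: form two strata with the configured stratifier (doubly-ranked by
default), compute the two-stratum Q, and keep the argmax. Ties in the argmax
go to the earlier candidate (candidates are RNG-ordered when subsampled) and
earlier proportion. Stopping: max Q < 3.84; either child below
`min_node_size` (1,000 by default — a biobank-scale value; simulation-scale
analyses in this package use 200–1,000); or depth 5 reached (nodes at the
maximum depth are not split further). Only three proportions are searched to
limit overfitting, since leaf estimates are computed on the same data that
chose the splits.

Child membership at fit time **is** the stratum assignment, not a covariate
threshold — thresholding would rebuild exactly the collider conditioning the
stratifier avoids, and for the same reason no "honest" split/estimate
subsample scheme is used. The boundary value (n₁M̄₁ + n₂M̄₂)/(n₁+n₂) of the
splitting covariate is stored per node purely to route new individuals
(ties route to the lower child). Every node records its own ratio estimate;
a node whose estimate is degenerate inherits its parent's, so predictions
are always defined.

The split search is implemented with grouped sums (one instrument ranking
shared across candidates per node, one lexsort per candidate, O(1) slope/SE
extraction per stratum), which keeps a full tree fit at n = 10,000 around
0.1–0.2 s on one core.

## Random forest of Q trees

`fit_rfqt` draws N_B bootstrap resamples of size n (with replacement), grows
one Q tree per resample, and at each node draws round(0.4·p) candidate
covariates (minimum 1) without replacement. Per-tree seeds are derived from
the master seed by tree index, so results do not depend on evaluation order.
The forest prediction is the unweighted mean of tree predictions. OOB
predictions average only trees whose bootstrap excludes the individual
(expected OOB fraction e⁻¹ per tree); individuals never OOB are flagged.

Variable importance permutes one covariate within a tree's OOB rows,
re-predicts, and averages the mean squared shift in predicted effects over
trees; covariates never used for splitting score exactly 0. Leaf sizes count
bootstrap multiplicity, so per tree they sum to n; S₁ is the mean over trees
of the size-weighted variance of leaf estimates, and S₂ the mean over trees
of the tree-level leaf Q (single-leaf trees contribute 0 to both). S₂
divides by the leaf-level association variances and is therefore less
sensitive than S₁ to the occasional exploding ratio estimate in a
weak-instrument leaf.

The permutation test applies **one shared row permutation to the whole
covariate block** (Z, X, Y untouched), refits the forest from scratch, and
repeats. Sharing the permutation across covariates preserves the joint
covariate distribution while severing covariate–(Z,X,Y) links, which is the
null of "no covariate modifies the effect". The p-value is the plain
proportion of null statistics ≥ observed; a flag applies the (r+1)/(n+1)
correction. Null forests may use a smaller N_B than the observed forest
(`N_B_null`) to trade compute for null-resolution; the default is the same
N_B. Bootstrap draws and tree seeds are redrawn independently in every
permutation replicate.

## Pooled stratum estimates

For decile-style presentation on a single covariate, the stratification is
repeated S times (default 100), each time dropping 10 random individuals —
enough to reshuffle ranks and expose the stratification variability.
Per-stratum association estimates are pooled with Rubin's rules: point
estimate = plain mean; within-variance U = mean σ̂²; between-variance
B = (S−1)⁻¹ Σ(β̂ᵢ − β̄)²; 95% CI = β̄ ± t_{v,0.975}·√(U + (1+1/S)B) with
v = (S−1)(1 + U/((1+1/S)B))². When B = 0 the t quantile degenerates; the
normal quantile is used and the event logged. The pooled ratio estimate is
β̄_Y/β̄_X with CI (L_Y/β̄_X, R_Y/β̄_X) (re-sorted when β̄_X < 0). The pooled
Q uses total variances U + (1+1/S)B in its denominator. The trend test is a
random-effects meta-regression of the pooled ratio estimates on the pooled
stratum covariate means: REML heterogeneity variance (bounded scalar
optimization on log τ², with an explicit τ² = 0 boundary check) and a Wald
z-test of the moderator slope. It is cross-checked against the reference R
meta-analysis implementation (`metafor::rma`) in the test suite.

## Simulator

The generator draws Z, U₁…U₂₀, ε_X, ε_Y iid N(0,1), with

    X  = 0.5 Z + 0.5 ΣU_j + ε_X
    M_j = b_j X + U_j
    Y  = (0.5 + Σ_{j≤5} γ_j M_j) X + 0.5 ΣU_j + ε_Y,

γ_j ~ N(γ, 0.1²) for the five modifiers (drawn once per dataset —
population-level modifier effects), 0 otherwise. Scenarios set b_j: A — all
0 (no colliders); B — 0.5 for even j (half the covariates are colliders);
C — 0.1 + 0.5·U_j per individual (collider strength modified by the
confounder, violating both the residual method's linearity and the
rank-preserving assumption). When p > 20 the extra covariates get their own
confounders that do not enter X or Y. `pure_null` forces every γ_j to
exactly 0 (true effect ≡ 0.5), enabling exact-null calibration studies that
γ = 0 alone does not give (the N(0, 0.1²) draws still induce weak
modification). The evaluation truth is the controlled direct effect
0.5 + Σγ_j M_j, a close, computationally simple stand-in for the total
effect targeted by MR estimates.

What the simulator does *not* emulate: non-normal or heavy-tailed traits,
discrete covariates, weak/invalid instruments beyond the built-in strength,
measurement error, or selection effects. Passing the simulation suite shows
the machinery is correct and well-calibrated under this linear-Gaussian
model, not that real-data estimates are unbiased when its assumptions fail.

## Problem sizes and reproducibility

Simulation evidence in the test suite and `scripts/acceptance.py` uses
desk-scale sizes chosen to make Monte-Carlo error small relative to the
effects checked: n = 2,000–10,000 per dataset, forests of 10–50 trees,
100–500 replicates for calibration rates, 99 permutations per permutation
test, and S = 50 resamples with K = 5 strata at n = 2,000 for pooled-CI
coverage. All randomness flows from explicit seeds; the same seed yields
bit-identical datasets, trees, and forests. CLI runs write a JSON manifest
(options + seed + version) alongside each artifact.

## Known limitations

- The χ² reference for Q is conservative in one-sample data (see above);
  use the permutation test for forest-level inference.
- Ratio estimates in small or weak-instrument strata can be extreme; S₁ and
  OOB MSE traces are sensitive to this, S₂ much less so.
- No confidence intervals for individual forest predictions.
- Stratification on a single covariate per node; multi-covariate
  stratification is the tree's job, not the stratifier's.
- The doubly-ranked rank-preserving assumption is untestable from data.
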