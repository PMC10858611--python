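# rfqt — heterogeneous causal effects in Mendelian randomization

`rfqt` investigates **effect heterogeneity** in Mendelian randomization (MR):
given individual-level data with a genetic instrument *Z* (a variant dosage or
weighted allele score), a continuous exposure *X*, an outcome *Y*, and a
high-dimensional set of candidate covariates *M₁…M_p*, it asks *for whom* the
causal effect of the exposure differs, and by how much.

The difficulty is that in MR the "randomization" happens at conception, so
almost every covariate is post-randomization: stratifying naively on a
covariate that is causally downstream of the exposure (a **collider**) breaks
the instrumental-variable assumptions inside the strata and biases
stratum-specific estimates. The package is built around stratification
methods that avoid this, and a data-adaptive forest that scales them to many
covariates. It is aimed at analysts of biobank-scale cohorts, and at
methodologists studying stratified instrumental-variable estimators.

## Method

**Collider-robust stratification.** The *doubly-ranked* method ranks
individuals by the instrument, forms consecutive pre-strata of 10, ranks by
the covariate within each pre-stratum, and assembles strata from equal
covariate-rank slices of every pre-stratum. Under a rank-preserving
assumption the resulting strata differ in covariate level but stay balanced
in the instrument. The *residual* method instead stratifies on the residual
of M regressed on Z (valid when the instrument acts linearly and
homogeneously on M).

**Stratum estimates and heterogeneity.** In stratum *k*, OLS of X on Z and
Y on Z give β̂_Xk (SE σ_Xk) and β̂_Yk (SE σ_Yk); the causal estimate is the
ratio θ̂_k = β̂_Yk/β̂_Xk. Heterogeneity across strata is measured by
Cochran's Q,

    Q = Σ_k (β̂_Yk − θ̂ β̂_Xk)² / (σ²_Yk + θ̂² σ²_Xk),

with θ̂ the inverse-variance-weighted average of the θ̂_k; under homogeneity
Q ~ χ²_{K−1}.

**Q trees and the RFQT.** A Q tree recursively splits a sample in two: at
each node every candidate covariate × splitting proportion (3:7, 5:5, 7:3)
is scored by the two-stratum Q, and the best split wins. Splitting stops
when max Q < 3.84 (the χ²₁ 95th percentile), when a child would fall below
the minimum node size (1,000 by default), or at depth 5. Leaves carry ratio
MR estimates. The random forest of Q trees (RFQT) bags such trees over
bootstrap resamples with a random 40% covariate subset per node; an
individual's estimate is the mean of the per-tree predictions. Out-of-bag
(OOB) predictions, permutation variable importance, and two permutation-test
statistics of heterogeneity (S₁, the size-weighted variance of leaf
estimates; S₂, the mean tree-level Q) are provided.

**Stabilized one-covariate strata.** For decile-type stratified estimates,
repeated stratification with 10 individuals dropped per iteration is pooled
with Rubin's rules (point estimate, U/B variance components, t-based CIs),
with a pooled Q statistic and a random-effects meta-regression trend test of
estimates against stratum covariate means.

A simulator generates datasets from a linear structural model with 20
confounders and known per-individual effects under three scenarios
(A: no colliders; B: half the covariates are colliders; C: collider effects
modified by confounders), for method evaluation by MSE against the known
truth.

## Worked example

```python
import numpy as np
from rfqt import (SimConfig, simulate_dataset, split_train_test,
                  QTreeHyperparameters, fit_rfqt, predict_rfqt,
                  variable_importance, evaluate_mse)

sim = simulate_dataset(SimConfig(n=10_000, scenario="A", gamma=0.5, seed=3))
train, test = split_train_test(sim.data, 2 / 3, seed=1)

forest = fit_rfqt(train, QTreeHyperparameters(min_node_size=1000), N_B=50, seed=2)
pred = predict_rfqt(forest, test.M)
truth = sim.true_effect[test.ids]
print(f"test MSE {evaluate_mse(pred, truth):.3f}, "
      f"corr(pred, truth) {np.corrcoef(pred, truth)[0, 1]:.2f}")
print(variable_importance(forest, train, seed=0).sort_values('rank').head(6))
```

Output:

```
test MSE 0.811, corr(pred, truth) 0.80
    importance  rank
M1    0.412473     1
M4    0.252787     2
M2    0.224447     3
M5    0.216421     4
M3    0.084174     5
M7    0.032451     6
```

The five simulated effect modifiers (M1–M5, modifier strength γ = 0.5)
occupy the top five importance ranks; the predicted per-individual effects
track the true controlled direct effects (mean 0.5) with correlation 0.80,
and the test MSE of 0.81 is well below the variance of the true effects
(≈ 1.4 here) that a constant prediction would incur.

The same pipeline is scriptable from the shell:

```bash
rfqt simulate --n 10000 --scenario A --gamma 0.5 --seed 3 --out data.csv
rfqt forest fit data.csv --instrument Z --exposure X --outcome Y \
    --covariates M1,...,M20 --n-trees 50 --out forest.json
rfqt forest predict forest.json data.csv ... --out predictions.csv
```

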