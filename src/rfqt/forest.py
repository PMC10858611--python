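"""Random forest of Q trees (RFQT).

Bootstrap-aggregated Q trees: each tree is grown on a with-replacement
resample of the training subset, and at every node only a random subset of
the covariates (40% by default) is considered, which de-correlates trees.
The forest estimate for an individual is the unweighted mean of the per-tree
predictions.

The module also provides:

- **out-of-bag (OOB) prediction** — each training individual is predicted
  only by the trees whose bootstrap excludes them;
- **permutation variable importance** — the mean (over trees) squared shift
  of OOB predicted effects after permuting one covariate among the OOB rows;
- **two permutation-test statistics of effect heterogeneity**:
  ``S1``, the mean over trees of the size-weighted variance of leaf MR
  estimates, and ``S2``, the mean over trees of the tree-level Cochran Q of
  its leaves.  S2 allows for variability in the instrument-exposure
  associations, making it more robust to weak instruments than S1.  Null
  distributions come from refitting the forest after jointly permuting the
  rows of the covariate block (one shared row permutation, which preserves
  covariate-covariate correlation while severing covariate links to the
  instrument, exposure and outcome).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Dataset
from .estimation import StratumEstimates, ivw_average, q_statistic
from .tree import QTree, QTreeHyperparameters, grow_qtree, predict_qtree

logger = logging.getLogger(__name__)

__all__ = [
    "Forest",
    "fit_rfqt",
    "predict_rfqt",
    "oob_predict",
    "variable_importance",
    "s1_statistic",
    "s2_statistic",
    "permutation_test",
    "PermTestResult",
]

DEFAULT_MTRY_FRACTION = 0.4


@dataclass
class Forest:
    """A fitted RFQT: trees plus their bootstrap index sets."""

    trees: list[QTree]
    bootstrap_ids: list[np.ndarray] | None
    hyper: QTreeHyperparameters
    n_train: int
    seed: int | None = None

    @property
    def N_B(self) -> int:
        return len(self.trees)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_train": self.n_train,
                "seed": self.seed,
                "trees": [json.loads(t.to_json()) for t in self.trees],
                "bootstrap_ids": None
                if self.bootstrap_ids is None
                else [b.tolist() for b in self.bootstrap_ids],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Forest":
        payload = json.loads(text)
        trees = [QTree.from_json(json.dumps(t)) for t in payload["trees"]]
        boots = payload["bootstrap_ids"]
        return cls(
            trees=trees,
            bootstrap_ids=None
            if boots is None
            else [np.asarray(b, dtype=np.int64) for b in boots],
            hyper=trees[0].hyper,
            n_train=payload["n_train"],
            seed=payload["seed"],
        )


def fit_rfqt(
    train: Dataset,
    hyper: QTreeHyperparameters | None = None,
    N_B: int = 200,
    seed: int = 0,
    bootstrap: bool = True,
) -> Forest:
    """Fit a forest of ``N_B`` Q trees on bootstrap resamples of ``train``.

    Per-tree seeds are derived from the master seed by tree index, so results
    are reproducible and independent of evaluation order.  A bootstrapped
    forest left at the single-tree default ``mtry_fraction=1.0`` is switched
    to the forest default of 0.4; pass an explicit fraction to override.
    With ``bootstrap=False`` every tree sees the full training sample
    (useful for the degenerate single-tree check; OOB logic is then
    unavailable).
    """
    if N_B < 1:
        raise ValueError("N_B must be at least 1")
    hyper = hyper or QTreeHyperparameters(min_node_size=1000)
    if hyper.mtry_fraction == 1.0 and bootstrap:
        hyper = hyper.replace(mtry_fraction=DEFAULT_MTRY_FRACTION)
    n = train.n
    child_seeds = np.random.SeedSequence(seed).spawn(N_B)
    trees = []
    boots: list[np.ndarray] | None = [] if bootstrap else None
    for i in range(N_B):
        rng = np.random.default_rng(child_seeds[i])
        if bootstrap:
            idx = rng.integers(0, n, size=n)
            boots.append(idx)
            sample = train.subset(idx)
        else:
            sample = train
        trees.append(grow_qtree(sample, hyper, seed=rng))
    return Forest(trees=trees, bootstrap_ids=boots, hyper=hyper, n_train=n, seed=seed)


def predict_rfqt(
    forest: Forest, M: np.ndarray, covariate_names: tuple[str, ...] | None = None
) -> np.ndarray:
    """Forest prediction: the arithmetic mean of per-tree predictions."""
    preds = np.stack(
        [predict_qtree(tree, M, covariate_names) for tree in forest.trees]
    )
    return preds.mean(axis=0)


def oob_predict(forest: Forest, train: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag predictions for the training individuals.

    Returns ``(estimates, counts)`` where ``counts[i]`` is the number of
    trees for which individual ``i`` was out of bag; estimates are NaN where
    the count is zero (or everywhere when the forest was fitted without
    bootstrap, in which case OOB is undefined).
    """
    n = train.n
    if forest.bootstrap_ids is None:
        logger.warning("forest was fitted without bootstrap; OOB is undefined")
        return np.full(n, np.nan), np.zeros(n, dtype=np.int64)
    total = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    for tree, boot in zip(forest.trees, forest.bootstrap_ids):
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        rows = np.nonzero(oob)[0]
        if rows.size == 0:
            continue
        total[rows] += predict_qtree(tree, train.M[rows], train.covariate_names)
        counts[rows] += 1
    with np.errstate(invalid="ignore"):
        est = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return est, counts


def variable_importance(
    forest: Forest, train: Dataset, seed: int = 0
) -> pd.DataFrame:
    """Permutation importance of each covariate on OOB individuals.

    For tree ``i`` and covariate ``m``: permute column ``m`` among the tree's
    OOB rows, re-predict, and record the mean squared shift
    ``D = mean_j (theta^m_j - theta_j)^2``; the importance of ``m`` is the
    mean of ``D`` over trees.  Covariates never used for splitting score
    exactly zero.  Returns a DataFrame indexed by covariate with columns
    ``importance`` and ``rank`` (1 = most important).
    """
    if forest.bootstrap_ids is None:
        raise ValueError("variable importance requires a bootstrapped forest")
    rng = np.random.default_rng(seed)
    names = train.covariate_names
    p = len(names)
    n = train.n
    D_sum = np.zeros(p)
    n_trees_used = 0
    for tree, boot in zip(forest.trees, forest.bootstrap_ids):
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        rows = np.nonzero(oob)[0]
        if rows.size == 0:
            continue
        n_trees_used += 1
        M_oob = train.M[rows]
        base = predict_qtree(tree, M_oob, names)
        used = {node.covariate for node in tree.nodes if node.covariate is not None}
        for j, name in enumerate(names):
            if name not in used:
                continue  # routing cannot change: D is exactly 0
            perm = rng.permutation(rows.size)
            M_perm = M_oob.copy()
            M_perm[:, j] = M_oob[perm, j]
            shifted = predict_qtree(tree, M_perm, names)
            D_sum[j] += np.mean((shifted - base) ** 2)
    if n_trees_used == 0:
        raise ValueError("forest has no nonempty OOB sets")
    importance = D_sum / n_trees_used
    order = np.argsort(-importance, kind="stable")
    rank = np.empty(p, dtype=np.int64)
    rank[order] = np.arange(1, p + 1)
    return pd.DataFrame({"importance": importance, "rank": rank}, index=list(names))


def _leaf_estimates(tree: QTree) -> StratumEstimates:
    leaves = tree.leaves()
    return StratumEstimates(
        beta_X=np.array([lf.beta_X for lf in leaves]),
        sigma_X=np.array([lf.sigma_X for lf in leaves]),
        beta_Y=np.array([lf.beta_Y for lf in leaves]),
        sigma_Y=np.array([lf.sigma_Y for lf in leaves]),
        theta=np.array([lf.theta for lf in leaves]),
        n_k=np.array([lf.n for lf in leaves]),
        mbar=np.full(len(leaves), np.nan),
        valid=np.array(
            [np.isfinite(lf.theta) and np.isfinite(lf.sigma_Y) for lf in leaves]
        ),
    )


def s1_statistic(forest: Forest) -> float:
    """Mean over trees of the size-weighted variance of leaf MR estimates.

    Leaf sizes count bootstrap multiplicity, so per tree they sum to the
    training size ``n``.
    """
    total = 0.0
    for tree in forest.trees:
        leaves = tree.leaves()
        sizes = np.array([lf.n for lf in leaves], dtype=float)
        thetas = np.array([lf.theta for lf in leaves])
        w = sizes / sizes.sum()
        mean = np.sum(w * thetas)
        total += float(np.sum(w * (thetas - mean) ** 2))
    return total / forest.N_B


def s2_statistic(forest: Forest) -> float:
    """Mean over trees of the tree-level Cochran Q of its leaves.

    A single-leaf tree contributes zero (its only leaf matches the tree-level
    IVW average exactly).
    """
    total = 0.0
    for tree in forest.trees:
        est = _leaf_estimates(tree)
        if int(est.valid.sum()) < 2:
            continue
        total += q_statistic(est).Q
    return total / forest.N_B


@dataclass(frozen=True)
class PermTestResult:
    """Observed S1/S2 with their permutation null distributions."""

    s1_observed: float
    s2_observed: float
    s1_null: np.ndarray
    s2_null: np.ndarray
    p1: float
    p2: float
    n_perm: int


def permutation_test(
    train: Dataset,
    hyper: QTreeHyperparameters | None = None,
    N_B: int = 100,
    n_perm: int = 100,
    seed: int = 0,
    N_B_null: int | None = None,
    plus_one: bool = False,
) -> PermTestResult:
    """Permutation test of effect heterogeneity via S1 and S2.

    The observed statistics come from a forest on ``train``.  Each null
    replicate applies one shared random row permutation to the whole
    covariate block (instrument, exposure and outcome untouched), refits a
    forest from scratch, and records S1/S2.  The p-value is the proportion of
    null statistics at least as large as the observed one; ``plus_one``
    applies the (r+1)/(n_perm+1) small-sample correction instead.
    ``N_B_null`` allows smaller null forests for tractability (default: same
    as observed).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    hyper = hyper or QTreeHyperparameters()
    seeds = np.random.SeedSequence(seed).spawn(n_perm + 2)
    forest = fit_rfqt(
        train, hyper, N_B=N_B, seed=int(seeds[0].generate_state(1)[0] % 2**31)
    )
    s1_obs = s1_statistic(forest)
    s2_obs = s2_statistic(forest)

    N_B_null = N_B if N_B_null is None else N_B_null
    s1_null = np.empty(n_perm)
    s2_null = np.empty(n_perm)
    for b in range(n_perm):
        rng = np.random.default_rng(seeds[b + 1])
        perm = rng.permutation(train.n)
        permuted = Dataset(
            ids=train.ids,
            Z=train.Z,
            X=train.X,
            Y=train.Y,
            M=train.M[perm],
            covariate_names=train.covariate_names,
        )
        null_forest = fit_rfqt(
            permuted,
            hyper,
            N_B=N_B_null,
            seed=int(rng.integers(2**31)),
        )
        s1_null[b] = s1_statistic(null_forest)
        s2_null[b] = s2_statistic(null_forest)

    def pval(null: np.ndarray, obs: float) -> float:
        r = int(np.sum(null >= obs))
        return (r + 1) / (n_perm + 1) if plus_one else r / n_perm

    return PermTestResult(
        s1_observed=s1_obs,
        s2_observed=s2_obs,
        s1_null=s1_null,
        s2_null=s2_null,
        p1=pval(s1_null, s1_obs),
        p2=pval(s2_null, s2_obs),
        n_perm=n_perm,
    )
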