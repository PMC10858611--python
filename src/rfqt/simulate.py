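"""Synthetic data generator for stratified Mendelian randomization.

The generator draws individual-level data from a linear structural model with
a single standard-normal instrument ``Z``, twenty independent standard-normal
unmeasured confounders ``U_j``, an exposure

    X = 0.5 Z + 0.5 * sum_j U_j + eps_X,

candidate covariates ``M_j = b_j X + U_j`` and an outcome

    Y = (0.5 + sum_{j<=5} gamma_j M_j) X + 0.5 * sum_j U_j + eps_Y,

with ``eps_X, eps_Y ~ N(0, 1)``.  The first five covariates are effect
modifiers: their coefficients ``gamma_j`` are drawn once per dataset from
``N(gamma, 0.1^2)`` where ``gamma`` is the strength of modification; the rest
have ``gamma_j = 0``.  Three scenarios control how the exposure feeds the
covariates:

- **A** — ``b_j = 0``: no covariate is a collider;
- **B** — ``b_j = 0.5`` for even ``j``: half the covariates are colliders
  (common effects of the exposure and a confounder);
- **C** — ``b_j = 0.1 + 0.5 U_j`` per individual: collider effects are
  modified by the confounders, violating both the linear-homogeneity
  assumption of residual stratification and the rank-preserving assumption.

Each simulated individual carries a known controlled direct effect
``0.5 + sum_{j<=5} gamma_j M_j``, used as the ground truth when scoring
predicted individual effects by mean squared error.  ``pure_null`` forces all
``gamma_j = 0`` exactly so the true effect is constant at 0.5 — with
``gamma = 0`` alone there remains weak modification from the N(0, 0.1^2)
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import Dataset, split_train_test

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "evaluate_mse",
    "run_method_grid",
]

N_CONFOUNDERS = 20


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated dataset."""

    n: int
    scenario: str = "A"
    gamma: float = 0.0
    p: int = 20
    n_modifiers: int = 5
    pure_null: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.scenario not in ("A", "B", "C"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 1 <= self.n_modifiers <= self.p:
            raise ValueError("n_modifiers must lie in 1..p")


@dataclass(frozen=True)
class SimulatedDataset:
    """A simulated Dataset plus its ground truth."""

    data: Dataset
    true_effect: np.ndarray
    gamma_j: np.ndarray
    config: SimConfig = field(repr=False, default=None)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Draw one dataset from the structural model under the given scenario."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n, config.p
    Z = rng.standard_normal(n)
    # one confounder per covariate; only the first 20 feed the exposure/outcome
    U = rng.standard_normal((n, max(N_CONFOUNDERS, p)))
    eps_X = rng.standard_normal(n)
    eps_Y = rng.standard_normal(n)
    u_sum = U[:, :N_CONFOUNDERS].sum(axis=1)
    X = 0.5 * Z + 0.5 * u_sum + eps_X

    if config.scenario == "A":
        b = np.zeros((1, p))
    elif config.scenario == "B":
        b = np.zeros((1, p))
        b[0, 1::2] = 0.5  # covariates M2, M4, ... are colliders
    else:  # scenario C: per-individual collider effects modified by U_j
        b = 0.1 + 0.5 * U[:, :p]
    M = b * X[:, None] + U[:, :p]

    gamma_j = np.zeros(p)
    if not config.pure_null:
        gamma_j[: config.n_modifiers] = rng.normal(
            config.gamma, 0.1, size=config.n_modifiers
        )
    true_effect = 0.5 + M @ gamma_j
    Y = true_effect * X + 0.5 * u_sum + eps_Y

    data = Dataset(
        ids=np.arange(n),
        Z=Z,
        X=X,
        Y=Y,
        M=M,
        covariate_names=tuple(f"M{j + 1}" for j in range(p)),
    )
    return SimulatedDataset(data=data, true_effect=true_effect, gamma_j=gamma_j, config=config)


def evaluate_mse(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared error of per-individual effect estimates against the
    controlled direct effects."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    return float(np.mean((predicted - truth) ** 2))


_STRATIFIERS = ("naive", "residual", "doubly_ranked")
METHOD_NAMES = ("none",) + tuple(
    f"{s}_{kind}" for s in _STRATIFIERS for kind in ("tree", "forest")
)


def _predict_with_method(method, train_sim, test_sim, hyper, n_trees, seed):
    # local imports avoid a circular dependency at module load
    from .estimation import stratum_associations
    from .forest import fit_rfqt, predict_rfqt
    from .stratify import StratumAssignment
    from .tree import grow_qtree, predict_qtree

    train, test = train_sim.data, test_sim.data
    if method == "none":
        one = StratumAssignment(np.ones(train.n, dtype=int), 1, (1.0,), "none")
        est = stratum_associations(train, one)
        return np.full(test.n, est.theta[0])
    stratifier, kind = method.rsplit("_", 1)
    hyper = hyper.replace(stratifier=stratifier)
    if kind == "tree":
        tree = grow_qtree(train, hyper.replace(mtry_fraction=1.0), seed=seed)
        return predict_qtree(tree, test.M, test.covariate_names)
    forest = fit_rfqt(train, hyper, N_B=n_trees, seed=seed)
    return predict_rfqt(forest, test.M, test.covariate_names)


def run_method_grid(
    scenarios,
    gammas,
    methods=METHOD_NAMES,
    n: int = 10_000,
    reps: int = 20,
    seed: int = 0,
    hyper=None,
    n_trees: int = 20,
    train_fraction: float = 2 / 3,
) -> pd.DataFrame:
    """Benchmark stratification/estimation method variants on simulated data.

    For every (scenario, gamma, replicate) a fresh dataset is simulated and
    split into train/test; each method is fitted on the training subset and
    its per-individual predictions on the test subset are scored against the
    controlled direct effects.  Returns a tidy DataFrame with one row per
    (scenario, gamma, method) holding the median test MSE across replicates.
    """
    from .tree import QTreeHyperparameters

    methods = tuple(methods)
    unknown = set(methods) - set(METHOD_NAMES)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if hyper is None:
        hyper = QTreeHyperparameters()
    seeds = np.random.SeedSequence(seed).generate_state(reps * 2 + 1)

    rows = []
    for scenario in scenarios:
        for gamma in gammas:
            mses = {m: [] for m in methods}
            for r in range(reps):
                sim = simulate_dataset(
                    SimConfig(n=n, scenario=scenario, gamma=gamma, seed=int(seeds[r]))
                )
                train_data, test_data = split_train_test(
                    sim.data, train_fraction, seed=int(seeds[reps + r])
                )
                train_sim = SimulatedDataset(
                    train_data, sim.true_effect[train_data.ids], sim.gamma_j, sim.config
                )
                test_sim = SimulatedDataset(
                    test_data, sim.true_effect[test_data.ids], sim.gamma_j, sim.config
                )
                for m in methods:
                    pred = _predict_with_method(
                        m, train_sim, test_sim, hyper, n_trees, int(seeds[2 * reps]) + r
                    )
                    mses[m].append(evaluate_mse(pred, test_sim.true_effect))
            for m in methods:
                rows.append(
                    {
                        "scenario": scenario,
                        "gamma": gamma,
                        "method": m,
                        "median_mse": float(np.median(mses[m])),
                        "reps": reps,
                    }
                )
    return pd.DataFrame(rows)
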