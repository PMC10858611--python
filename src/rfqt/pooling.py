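"""Stabilized stratum-specific estimates by repeated subsampling.

Doubly-ranked stratification depends on rank orderings, so a one-shot
stratification can be noticeably variable: removing a handful of individuals
reshuffles ranks and can move individuals between strata.  To stabilize the
stratum-specific estimates we repeat the stratification ``S`` times, each
time randomly excluding a small number of individuals (10 by default), and
combine the per-resample association estimates with Rubin's rules:

- pooled point estimate: the plain mean over resamples,
  ``beta_P = mean_i beta_i``;
- within-resample variance ``U = mean_i sigma_i^2`` and between-resample
  variance ``B = var_i(beta_i)`` (with the S-1 denominator);
- 95% CI ``beta_P +/- t_{v, 0.975} * sqrt(U + (1 + 1/S) B)`` with
  Satterthwaite-type degrees of freedom
  ``v = (S-1) (1 + U / ((1 + 1/S) B))^2``.

The pooled ratio estimate per stratum is ``beta_P_Y / beta_P_X`` with CI
``(L_Y / beta_P_X, R_Y / beta_P_X)``.  A pooled Cochran Q uses the total
variances ``U + (1 + 1/S) B`` in its denominator, and a trend test regresses
the pooled stratum estimates on the pooled stratum covariate means with a
random-effects meta-regression (REML heterogeneity variance, Wald test of
the moderator slope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import Dataset
from .estimation import grouped_ols
from .stratify import doubly_ranked_deciles

logger = logging.getLogger(__name__)

__all__ = [
    "PooledEstimates",
    "pooled_stratum_estimates",
    "pooled_q",
    "trend_test",
    "meta_regression",
]


@dataclass(frozen=True)
class PooledEstimates:
    """Rubin's-rules-pooled stratum estimates from ``S`` resamples."""

    beta_X: np.ndarray
    beta_Y: np.ndarray
    U_X: np.ndarray
    U_Y: np.ndarray
    B_X: np.ndarray
    B_Y: np.ndarray
    df: np.ndarray  # Satterthwaite df v_k for the outcome associations
    ci_Y: np.ndarray  # (K, 2) intervals for beta_Y
    theta: np.ndarray  # pooled ratio estimates
    ci_theta: np.ndarray  # (K, 2)
    mbar: np.ndarray
    S: int
    K: int
    covariate_name: str | None = None

    def total_var_X(self) -> np.ndarray:
        return self.U_X + (1 + 1 / self.S) * self.B_X

    def total_var_Y(self) -> np.ndarray:
        return self.U_Y + (1 + 1 / self.S) * self.B_Y

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": np.arange(1, self.K + 1),
                "covariate_mean": self.mbar,
                "beta_X": self.beta_X,
                "beta_Y": self.beta_Y,
                "estimate": self.theta,
                "ci_lower": self.ci_theta[:, 0],
                "ci_upper": self.ci_theta[:, 1],
            }
        )


def _rubin(beta: np.ndarray, sigma: np.ndarray) -> tuple[np.ndarray, ...]:
    """Pool an (S, K) matrix of estimates and SEs by Rubin's rules."""
    S = beta.shape[0]
    pooled = beta.mean(axis=0)
    U = np.mean(sigma**2, axis=0)
    B = np.var(beta, axis=0, ddof=1)
    return pooled, U, B


def _ci(pooled, U, B, S):
    total = U + (1 + 1 / S) * B
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (S - 1) * (1 + U / ((1 + 1 / S) * B)) ** 2
    # B = 0: no between-resample variability; fall back to a normal quantile
    zero_B = ~(B > 0)
    if zero_B.any():
        logger.info(
            "between-resample variance is zero in %d strata; using normal quantiles",
            int(zero_B.sum()),
        )
        df = np.where(zero_B, np.inf, df)
    t = np.where(np.isinf(df), stats.norm.ppf(0.975), stats.t.ppf(0.975, df))
    half = t * np.sqrt(total)
    return df, np.column_stack([pooled - half, pooled + half])


def pooled_stratum_estimates(
    data: Dataset,
    covariate: str,
    K: int = 10,
    S: int = 100,
    seed: int = 0,
    n_drop: int = 10,
    prestratum_size: int = 10,
) -> PooledEstimates:
    """Pooled doubly-ranked stratum estimates over ``S`` drop-``n_drop``
    resamples.

    Each iteration drops ``n_drop`` uniformly-random individuals (sampled
    independently across iterations), forms ``K`` equal doubly-ranked strata
    on ``covariate``, and records the per-stratum instrument-exposure and
    instrument-outcome associations and the stratum covariate means, which
    are then pooled.
    """
    if S < 2:
        raise ValueError("S must be at least 2 (between-variance undefined)")
    if data.n <= n_drop:
        raise ValueError("dataset too small for the drop-resampling scheme")
    rng = np.random.default_rng(seed)
    cov = data.covariate(covariate)

    bX = np.empty((S, K))
    sX = np.empty((S, K))
    bY = np.empty((S, K))
    sY = np.empty((S, K))
    mb = np.empty((S, K))
    for i in range(S):
        keep = np.setdiff1d(
            np.arange(data.n), rng.choice(data.n, size=n_drop, replace=False)
        )
        assign = doubly_ranked_deciles(
            data.Z[keep], cov[keep], K=K, seed=rng, prestratum_size=prestratum_size
        )
        bX[i], sX[i], n_k = grouped_ols(data.Z[keep], data.X[keep], assign.labels, K)
        bY[i], sY[i], _ = grouped_ols(data.Z[keep], data.Y[keep], assign.labels, K)
        mb[i] = (
            np.bincount(assign.labels, weights=cov[keep], minlength=K + 1)[1:] / n_k
        )

    beta_X, U_X, B_X = _rubin(bX, sX)
    beta_Y, U_Y, B_Y = _rubin(bY, sY)
    df, ci_Y = _ci(beta_Y, U_Y, B_Y, S)
    theta = beta_Y / beta_X
    ci_theta = ci_Y / beta_X[:, None]
    ci_theta = np.sort(ci_theta, axis=1)  # negative beta_X flips the interval
    return PooledEstimates(
        beta_X=beta_X,
        beta_Y=beta_Y,
        U_X=U_X,
        U_Y=U_Y,
        B_X=B_X,
        B_Y=B_Y,
        df=df,
        ci_Y=ci_Y,
        theta=theta,
        ci_theta=ci_theta,
        mbar=mb.mean(axis=0),
        S=S,
        K=K,
        covariate_name=covariate,
    )


def pooled_q(pooled: PooledEstimates) -> tuple[float, float]:
    """Cochran Q over the pooled stratum estimates, with total variances
    ``U + (1 + 1/S) B`` in the denominator; returns ``(Q_P, p_value)``."""
    if pooled.K < 2:
        raise ValueError("pooled Q requires at least 2 strata")
    vX = pooled.total_var_X()
    vY = pooled.total_var_Y()
    se = np.sqrt(vY) / np.abs(pooled.beta_X)
    w = 1.0 / se**2
    theta_hat = float(np.sum(w * pooled.theta) / np.sum(w))
    Q = float(
        np.sum(
            (pooled.beta_Y - theta_hat * pooled.beta_X) ** 2
            / (vY + theta_hat**2 * vX)
        )
    )
    p = float(stats.chi2.sf(Q, pooled.K - 1))
    return Q, p


def meta_regression(
    estimates: np.ndarray, variances: np.ndarray, moderator: np.ndarray
) -> tuple[float, float, float, float]:
    """Random-effects meta-regression with REML heterogeneity variance.

    Fits ``y_k = b0 + b1 * x_k + u_k + e_k`` with ``u_k ~ N(0, tau2)`` and
    ``e_k ~ N(0, v_k)``; returns ``(slope, slope_se, p_value, tau2)`` with a
    Wald z-test of the moderator slope.
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    x = np.asarray(moderator, dtype=float)
    K = y.size
    if K < 3:
        raise ValueError("meta-regression requires at least 3 strata")
    design = np.column_stack([np.ones(K), x])

    def fit_wls(tau2):
        w = 1.0 / (v + tau2)
        xtw = design.T * w
        cov_inv = xtw @ design
        cov = np.linalg.inv(cov_inv)
        b = cov @ (xtw @ y)
        return b, cov, w

    def neg_reml(log_tau2):
        tau2 = np.exp(log_tau2)
        b, cov, w = fit_wls(tau2)
        resid = y - design @ b
        _, logdet = np.linalg.slogdet(design.T @ (design * w[:, None]))
        return 0.5 * (-np.sum(np.log(w)) + logdet + np.sum(w * resid**2))

    scale = max(float(np.mean(v)), 1e-12)
    res = optimize.minimize_scalar(
        neg_reml, bounds=(np.log(scale * 1e-8), np.log(scale * 1e6)), method="bounded"
    )
    tau2 = float(np.exp(res.x))
    if neg_reml(np.log(scale * 1e-10)) <= res.fun:  # boundary: tau2 -> 0
        tau2 = 0.0
    b, cov, _ = fit_wls(tau2)
    slope = float(b[1])
    se = float(np.sqrt(cov[1, 1]))
    p = float(2 * stats.norm.sf(abs(slope) / se))
    return slope, se, p, tau2


def trend_test(pooled: PooledEstimates) -> tuple[float, float, float]:
    """Trend of pooled stratum MR estimates against stratum covariate means.

    Returns ``(slope, se, p_value)`` from the random-effects meta-regression
    with the stratum covariate mean as moderator.
    """
    var_theta = pooled.total_var_Y() / pooled.beta_X**2
    slope, se, p, _ = meta_regression(pooled.theta, var_theta, pooled.mbar)
    return slope, se, p
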