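"""Stratum-specific instrumental-variable estimates and heterogeneity.

For each stratum ``k`` we regress the exposure and the outcome on the
instrument (OLS with intercept), giving the instrument-exposure association
``beta_Xk`` (SE ``sigma_Xk``) and the instrument-outcome association
``beta_Yk`` (SE ``sigma_Yk``).  The stratum-specific causal estimate is the
ratio ``theta_k = beta_Yk / beta_Xk``.

Heterogeneity between the stratum estimates is measured by Cochran's Q,

    Q = sum_k (beta_Yk - theta_hat * beta_Xk)^2
              / (sigma_Yk^2 + theta_hat^2 * sigma_Xk^2),

with ``theta_hat`` the inverse-variance weighted (IVW) average of the ratio
estimates.  Under homogeneity Q follows a chi-squared distribution with K-1
degrees of freedom.  Because the denominator carries the uncertainty of the
instrument-exposure association, the statistic remains well calibrated when
instruments are weak within strata — important here, since stratification
shrinks per-stratum sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datasets import Dataset
from .stratify import StratumAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "StratumEstimates",
    "QResult",
    "stratum_associations",
    "ivw_average",
    "q_statistic",
    "grouped_ols",
]


class UndefinedRatioError(ZeroDivisionError):
    """The instrument-exposure association is exactly zero in a stratum."""


@dataclass(frozen=True)
class StratumEstimates:
    """Per-stratum association and ratio estimates.

    Strata that could not be estimated (constant instrument, or fewer than 3
    members) are flagged ``valid=False`` and excluded from IVW and Q.
    """

    beta_X: np.ndarray
    sigma_X: np.ndarray
    beta_Y: np.ndarray
    sigma_Y: np.ndarray
    theta: np.ndarray
    n_k: np.ndarray
    mbar: np.ndarray
    valid: np.ndarray
    covariate_name: str | None = None

    @property
    def K(self) -> int:
        return self.beta_X.size

    def ratio_se(self) -> np.ndarray:
        """First-order standard error of the ratio estimate,
        ``sigma_Yk / |beta_Xk|``."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.sigma_Y / np.abs(self.beta_X)


@dataclass(frozen=True)
class QResult:
    Q: float
    df: int
    p_value: float
    theta_hat: float
    K: int


def grouped_ols(
    z: np.ndarray, w: np.ndarray, labels: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group OLS slope and classical SE of ``w`` on ``z`` with intercept.

    Returns ``(beta, se, n_k)`` arrays of length K (group k at index k-1);
    entries are NaN where the group has fewer than 3 members or constant
    ``z``.  Implemented with grouped sums so it stays fast inside tree search.
    """
    n_k = np.bincount(labels, minlength=K + 1)[1:].astype(float)
    sz = np.bincount(labels, weights=z, minlength=K + 1)[1:]
    sw = np.bincount(labels, weights=w, minlength=K + 1)[1:]
    szz = np.bincount(labels, weights=z * z, minlength=K + 1)[1:]
    szw = np.bincount(labels, weights=z * w, minlength=K + 1)[1:]
    sww = np.bincount(labels, weights=w * w, minlength=K + 1)[1:]

    with np.errstate(divide="ignore", invalid="ignore"):
        czz = szz - sz * sz / n_k
        czw = szw - sz * sw / n_k
        cww = sww - sw * sw / n_k
        beta = czw / czz
        ssr = np.maximum(cww - czw * czw / czz, 0.0)
        se = np.sqrt(ssr / (n_k - 2.0) / czz)
    bad = (n_k < 3) | ~(czz > 0)
    beta[bad] = np.nan
    se[bad] = np.nan
    return beta, se, n_k.astype(np.int64)


def stratum_associations(
    data: Dataset,
    assignment: StratumAssignment,
    covariate: str | np.ndarray | None = None,
) -> StratumEstimates:
    """Instrument-exposure/outcome associations and ratio estimates per stratum.

    ``covariate`` (name or vector) supplies the stratifying covariate whose
    per-stratum mean ``mbar_k`` is recorded; defaults to the assignment's
    covariate name when set.
    """
    labels = assignment.labels
    if labels.size != data.n:
        raise ValueError("assignment length does not match dataset")
    K = assignment.K
    beta_X, sigma_X, n_k = grouped_ols(data.Z, data.X, labels, K)
    beta_Y, sigma_Y, _ = grouped_ols(data.Z, data.Y, labels, K)

    valid = np.isfinite(beta_X) & np.isfinite(beta_Y)
    if not valid.all():
        logger.warning(
            "%d of %d strata could not be estimated (constant instrument or "
            "too few members); they are excluded from IVW/Q",
            int((~valid).sum()),
            K,
        )
    if np.any(valid & (beta_X == 0)):
        raise UndefinedRatioError(
            "instrument-exposure association is exactly zero in a stratum"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = beta_Y / beta_X

    cov_name = None
    if covariate is None and assignment.covariate_name is not None:
        covariate = assignment.covariate_name
    if isinstance(covariate, str):
        cov_name = covariate
        covariate = data.covariate(covariate)
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
        with np.errstate(invalid="ignore"):
            mbar = (
                np.bincount(labels, weights=covariate, minlength=K + 1)[1:]
                / np.maximum(n_k, 1)
            )
        mbar[n_k == 0] = np.nan
    else:
        mbar = np.full(K, np.nan)

    return StratumEstimates(
        beta_X=beta_X,
        sigma_X=sigma_X,
        beta_Y=beta_Y,
        sigma_Y=sigma_Y,
        theta=theta,
        n_k=n_k,
        mbar=mbar,
        valid=valid,
        covariate_name=cov_name,
    )


def _usable(est: StratumEstimates) -> np.ndarray:
    return est.valid & np.isfinite(est.theta)


def ivw_average(est: StratumEstimates) -> float:
    """Inverse-variance weighted average of the stratum ratio estimates.

    Weights are ``1 / se_k^2`` with the first-order ratio SE
    ``se_k = sigma_Yk / |beta_Xk|``.  Strata with an exactly-zero SE (perfect
    fit) carry infinite weight; if any exist, their plain average is returned.
    """
    use = _usable(est)
    if not use.any():
        raise ValueError("no usable strata for IVW averaging")
    theta = est.theta[use]
    se = est.ratio_se()[use]
    if np.any(se == 0):
        return float(theta[se == 0].mean())
    w = 1.0 / se**2
    return float(np.sum(w * theta) / np.sum(w))


def _q_at(theta: float, est: StratumEstimates, use: np.ndarray) -> float:
    num = (est.beta_Y[use] - theta * est.beta_X[use]) ** 2
    den = est.sigma_Y[use] ** 2 + theta**2 * est.sigma_X[use] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((num == 0) & (den == 0), 0.0, num / den)
    return float(np.sum(terms))


def q_statistic(est: StratumEstimates, iterate_theta: bool = False) -> QResult:
    """Cochran's Q over the usable strata, with a chi-squared(K-1) p-value.

    By default ``theta_hat`` is the (fixed) IVW average; with
    ``iterate_theta=True`` it is instead chosen to minimize Q, the
    profile-likelihood variant.
    """
    use = _usable(est)
    K_use = int(use.sum())
    if K_use < 2:
        raise ValueError("Q requires at least 2 usable strata")
    theta_hat = ivw_average(est)
    if iterate_theta:
        res = optimize.minimize_scalar(
            lambda t: _q_at(t, est, use),
            bracket=(theta_hat - 1.0, theta_hat + 1.0),
        )
        theta_hat = float(res.x)
    Q = _q_at(theta_hat, est, use)
    df = K_use - 1
    p = float(stats.chi2.sf(Q, df))
    return QResult(Q=Q, df=df, p_value=p, theta_hat=theta_hat, K=K_use)
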