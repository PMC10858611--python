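"""Stratification of a sample on a single covariate.

Three methods are provided:

``naive``
    Sort individuals by the covariate and cut the ranks into contiguous
    blocks.  Simple, but if the covariate sits causally downstream of the
    instrument (a collider), naive strata re-introduce confounding into the
    instrumental-variable analysis within each stratum.

``residual``
    Regress the covariate on the instrument (OLS with intercept), then apply
    the naive cut to the residuals.  Under a linear, homogeneous instrument
    effect ``M = M(0) + alpha * Z`` the residual recovers the counterfactual
    covariate ``M(0)``, which is not a function of the instrument.

``doubly_ranked``
    Rank individuals by the instrument, form consecutive pre-strata of fixed
    size (10 by default), rank by the covariate within each pre-stratum, and
    assemble strata by covariate-rank range across pre-strata.  This only
    needs a rank-preserving assumption — that an individual's counterfactual
    covariate values keep the same rank ordering across instrument values —
    and balances the instrument distribution across strata by construction.

All rank ties are broken at random from a single seeded RNG stream per call,
so results are reproducible and invariant to the input row order up to that
stream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StratumAssignment",
    "naive_strata",
    "residual_strata",
    "doubly_ranked_strata",
    "doubly_ranked_deciles",
    "largest_remainder_quotas",
]

#: Default number of individuals per instrument pre-stratum.
DEFAULT_PRESTRATUM_SIZE = 10


@dataclass(frozen=True)
class StratumAssignment:
    """Per-individual stratum labels in ``1..K``."""

    labels: np.ndarray
    K: int
    proportions: tuple[float, ...]
    method: str
    covariate_name: str | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "proportions", tuple(self.proportions))
        if labels.size and (labels.min() < 1 or labels.max() > self.K):
            raise ValueError("labels must lie in 1..K")

    @property
    def n(self) -> int:
        return self.labels.size

    def sizes(self) -> np.ndarray:
        """Realized stratum sizes, index k-1 holds the size of stratum k."""
        return np.bincount(self.labels, minlength=self.K + 1)[1:]


def _check_proportions(proportions) -> np.ndarray:
    props = np.asarray(proportions, dtype=float)
    if props.ndim != 1 or props.size < 1:
        raise ValueError("proportions must be a 1-D sequence")
    if np.any(props <= 0):
        raise ValueError("proportions must be positive")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    return props


def largest_remainder_quotas(proportions: np.ndarray, size: int) -> np.ndarray:
    """Integer stratum quotas for ``size`` individuals by largest remainder.

    Floors ``proportions * size`` and hands the leftover units to the largest
    fractional remainders (ties to the lower stratum index), so the quotas
    always sum to ``size`` and deviate from the targets by less than 1.
    """
    props = np.asarray(proportions, dtype=float)
    raw = props * size
    quotas = np.floor(raw).astype(np.int64)
    leftover = size - quotas.sum()
    if leftover > 0:
        remainders = raw - quotas
        # stable argsort descending: ties go to the lower index
        order = np.argsort(-remainders, kind="stable")
        quotas[order[:leftover]] += 1
    return quotas


def _cut_by_rank(rank: np.ndarray, quotas: np.ndarray) -> np.ndarray:
    """Map within-group ranks (0-based) to stratum labels 1..K via quotas."""
    bounds = np.cumsum(quotas)
    return np.searchsorted(bounds, rank, side="right") + 1


def _random_rank(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """0-based ranks of ``values`` with ties broken at random."""
    n = values.size
    order = np.lexsort((rng.random(n), values))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    return rank


def naive_strata(values, proportions, seed: int | np.random.Generator = 0) -> StratumAssignment:
    """Cut individuals into contiguous covariate-rank blocks.

    Ties are broken at random (seeded); realized sizes follow the target
    proportions by largest-remainder rounding.
    """
    values = np.asarray(values, dtype=float)
    props = _check_proportions(proportions)
    n = values.size
    if props.size > n:
        raise ValueError(f"cannot form {props.size} strata from {n} individuals")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rank = _random_rank(values, rng)
    quotas = largest_remainder_quotas(props, n)
    labels = _cut_by_rank(rank, quotas)
    return StratumAssignment(labels, props.size, tuple(props), "naive")


def residual_strata(
    covariate, instrument, proportions, seed: int | np.random.Generator = 0
) -> StratumAssignment:
    """Stratify on the residual of the covariate regressed on the instrument."""
    covariate = np.asarray(covariate, dtype=float)
    instrument = np.asarray(instrument, dtype=float)
    z_centered = instrument - instrument.mean()
    szz = z_centered @ z_centered
    if szz <= 0:
        raise ValueError("instrument is constant: residual regression is degenerate")
    alpha = (z_centered @ covariate) / szz
    residuals = covariate - alpha * z_centered  # intercept drops out of ranks
    assignment = naive_strata(residuals, proportions, seed)
    return StratumAssignment(
        assignment.labels, assignment.K, assignment.proportions, "residual"
    )


def _warn_if_discrete(values: np.ndarray) -> None:
    if values.size and np.unique(values).size <= max(10, values.size // 50):
        warnings.warn(
            "covariate takes few distinct values; doubly-ranked stratification "
            "on a discrete covariate should be interpreted with caution",
            UserWarning,
            stacklevel=3,
        )


def doubly_ranked_strata(
    instrument,
    covariate,
    proportions,
    seed: int | np.random.Generator = 0,
    prestratum_size: int = DEFAULT_PRESTRATUM_SIZE,
) -> StratumAssignment:
    """Doubly-ranked stratification on one covariate.

    Steps: (1) rank by instrument, ties at random; (2) form consecutive
    pre-strata of ``prestratum_size`` (the final pre-stratum may be smaller);
    (3) rank by covariate within each pre-stratum, ties at random; (4) cut
    each pre-stratum's covariate-rank range by the target proportions
    (largest-remainder rounding on the pre-stratum's own size) and concatenate
    the labels.  Each full pre-stratum therefore contributes the same number
    of individuals to every stratum, which balances the instrument across
    strata.
    """
    instrument = np.asarray(instrument, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    props = _check_proportions(proportions)
    n = instrument.size
    if n == 0:
        raise ValueError("cannot stratify an empty sample")
    if props.size > min(n, prestratum_size):
        raise ValueError(
            f"cannot form {props.size} strata with pre-strata of size {prestratum_size}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    _warn_if_discrete(covariate)

    # pre-stratum id per individual, from the instrument ranking
    z_rank = _random_rank(instrument, rng)
    prestratum = z_rank // prestratum_size

    labels = np.empty(n, dtype=np.int64)
    # sort by (pre-stratum, covariate, random) to get within-pre-stratum ranks
    order = np.lexsort((rng.random(n), covariate, prestratum))
    sizes = np.bincount(prestratum)
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    within_rank = np.arange(n) - starts[prestratum[order]]

    quota_cache: dict[int, np.ndarray] = {}
    for s in np.unique(sizes):
        quota_cache[int(s)] = largest_remainder_quotas(props, int(s))
    sorted_labels = np.empty(n, dtype=np.int64)
    for s, quotas in quota_cache.items():
        mask = sizes[prestratum[order]] == s
        sorted_labels[mask] = _cut_by_rank(within_rank[mask], quotas)
    labels[order] = sorted_labels
    return StratumAssignment(labels, props.size, tuple(props), "doubly_ranked")


def doubly_ranked_deciles(
    instrument,
    covariate,
    K: int = 10,
    seed: int | np.random.Generator = 0,
    prestratum_size: int = DEFAULT_PRESTRATUM_SIZE,
) -> StratumAssignment:
    """Doubly-ranked stratification into ``K`` equal-proportion strata."""
    if K < 2:
        raise ValueError("K must be at least 2")
    return doubly_ranked_strata(
        instrument,
        covariate,
        np.full(K, 1.0 / K),
        seed=seed,
        prestratum_size=prestratum_size,
    )
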