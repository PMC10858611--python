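"""Individual-level data container and tabular I/O.

A :class:`Dataset` holds aligned per-individual vectors for a single-sample
instrumental-variable analysis: an instrument ``Z`` (a genetic variant dosage
or a weighted allele score), a continuous exposure ``X``, a continuous outcome
``Y``, and a matrix ``M`` of candidate covariates that may modify the causal
effect of the exposure.  All downstream machinery (stratification, Q trees,
forests, pooling) operates on this container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnConfig",
    "Dataset",
    "load_dataset",
    "split_train_test",
    "weighted_score",
]


class ConfigurationError(ValueError):
    """A column-role configuration does not match the data."""


class EmptyDataError(ValueError):
    """No usable rows remain after complete-case filtering."""


@dataclass(frozen=True)
class ColumnConfig:
    """Mapping of column names to analysis roles.

    The instrument, exposure and outcome roles must name distinct columns.
    The exposure may additionally be included among the candidate covariates
    (``include_exposure_as_covariate``) so that a non-linear effect of the
    exposure itself can be detected as effect heterogeneity.
    """

    instrument_col: str
    exposure_col: str
    outcome_col: str
    covariate_cols: tuple[str, ...]
    include_exposure_as_covariate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariate_cols", tuple(self.covariate_cols))
        core = (self.instrument_col, self.exposure_col, self.outcome_col)
        if len(set(core)) != 3:
            raise ConfigurationError(
                "instrument, exposure and outcome must be distinct columns"
            )
        if len(set(self.covariate_cols)) != len(self.covariate_cols):
            raise ConfigurationError("duplicate covariate column names")
        for col in (self.instrument_col, self.outcome_col):
            if col in self.covariate_cols:
                raise ConfigurationError(
                    f"column {col!r} cannot be both a covariate and a core role"
                )


@dataclass(frozen=True)
class Dataset:
    """Aligned per-individual data for a stratified MR analysis.

    Attributes
    ----------
    ids : ndarray
        Individual identifiers (any dtype, unique per row).
    Z, X, Y : ndarray of float
        Instrument, exposure and outcome vectors of common length ``n``.
    M : ndarray of float, shape (n, p)
        Candidate covariate matrix.
    covariate_names : tuple of str
        Column names of ``M`` (unique, non-empty).
    """

    ids: np.ndarray
    Z: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    M: np.ndarray
    covariate_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", np.asarray(self.ids))
        for name in ("Z", "X", "Y"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        M = np.atleast_2d(np.asarray(self.M, dtype=float))
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        n = len(self.ids)
        if n < 1:
            raise EmptyDataError("dataset must contain at least one individual")
        if not (len(self.Z) == len(self.X) == len(self.Y) == self.M.shape[0] == n):
            raise ValueError("all columns must have identical length")
        if self.M.shape[1] != len(self.covariate_names):
            raise ValueError("covariate_names must match the number of M columns")
        if any(not name for name in self.covariate_names):
            raise ValueError("covariate names must be non-empty")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValueError("covariate names must be unique")
        for arr in (self.Z, self.X, self.Y, self.M):
            if not np.all(np.isfinite(arr)):
                raise ValueError("dataset contains missing or non-finite values")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return self.M.shape[1]

    def covariate(self, name: str) -> np.ndarray:
        """Return one covariate column by name."""
        try:
            j = self.covariate_names.index(name)
        except ValueError:
            raise KeyError(f"unknown covariate {name!r}") from None
        return self.M[:, j]

    def subset(self, index: np.ndarray) -> "Dataset":
        """Row-subset (or resample, if ``index`` has duplicates) the dataset."""
        index = np.asarray(index)
        return replace(
            self,
            ids=self.ids[index],
            Z=self.Z[index],
            X=self.X[index],
            Y=self.Y[index],
            M=self.M[index],
        )

    def to_frame(self, config: ColumnConfig | None = None) -> pd.DataFrame:
        """Export as a DataFrame with an ``id`` column (round-trips with
        :func:`load_dataset`)."""
        if config is None:
            cols = {"id": self.ids, "Z": self.Z, "X": self.X, "Y": self.Y}
        else:
            cols = {
                "id": self.ids,
                config.instrument_col: self.Z,
                config.exposure_col: self.X,
                config.outcome_col: self.Y,
            }
        frame = pd.DataFrame(cols)
        for j, name in enumerate(self.covariate_names):
            if name not in frame.columns:
                frame[name] = self.M[:, j]
        return frame


def dataset_from_frame(frame: pd.DataFrame, config: ColumnConfig) -> Dataset:
    """Build a Dataset from an in-memory DataFrame (complete cases only)."""
    needed = [config.instrument_col, config.exposure_col, config.outcome_col]
    needed += [c for c in config.covariate_cols if c not in needed]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"missing columns: {missing}")

    sub = frame[needed].apply(pd.to_numeric, errors="raise")
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing values", n_dropped)
    sub = sub[keep]
    if sub.empty:
        raise EmptyDataError("no complete-case rows remain")

    ids = frame.index[keep].to_numpy() if "id" not in frame.columns else frame.loc[keep, "id"].to_numpy()
    cov_names = list(config.covariate_cols)
    if config.include_exposure_as_covariate and config.exposure_col not in cov_names:
        cov_names.append(config.exposure_col)
    return Dataset(
        ids=ids,
        Z=sub[config.instrument_col].to_numpy(),
        X=sub[config.exposure_col].to_numpy(),
        Y=sub[config.outcome_col].to_numpy(),
        M=sub[cov_names].to_numpy(),
        covariate_names=tuple(cov_names),
    )


def load_dataset(path, config: ColumnConfig) -> Dataset:
    """Load a CSV/TSV file with a header row into a :class:`Dataset`.

    Rows with any missing value in a used column are dropped (complete-case
    rule) and the drop count is logged.  Non-numeric content in a used column
    raises rather than being silently coerced.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    return dataset_from_frame(frame, config)


def split_train_test(
    data: Dataset, train_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Randomly partition individuals into disjoint train/test subsets.

    ``train`` receives ``round(n * train_fraction)`` individuals; the split is
    reproducible for a fixed seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    n_train = int(round(data.n * train_fraction))
    if n_train == 0 or n_train == data.n:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty subset at n={data.n}"
        )
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return data.subset(train_idx), data.subset(test_idx)


def weighted_score(dosages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Combine variant dosages into a weighted allele score.

    Parameters
    ----------
    dosages : ndarray, shape (n, v)
        Per-individual dosages for ``v`` variants.
    weights : ndarray, shape (v,)
        Per-variant weights (e.g. external GWAS effect sizes).

    Returns
    -------
    ndarray, shape (n,)
        ``score_i = sum_v weights_v * dosages_iv``.
    """
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if dosages.shape[1] != weights.shape[0]:
        raise ValueError(
            f"dosage matrix has {dosages.shape[1]} variants but "
            f"{weights.shape[0]} weights were given"
        )
    return dosages @ weights
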