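"""Dataset container, validation, and exposure standardization.

A mixtures analysis operates on a rectangular table with one outcome column
(continuous, or binary 0/1 for the probit family), M exposure columns forming
the argument of the exposure-response surface h, P covariate columns entering
linearly, and optionally a cluster-id column for repeated-measures /
family-clustered outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FAMILIES",
    "MixtureDataset",
    "validate_dataset",
    "standardize_exposures",
]

FAMILIES = ("gaussian", "binomial-probit")


@dataclass
class MixtureDataset:
    """In-memory (y, Z, X) triple plus optional cluster labels.

    Attributes
    ----------
    y : ndarray, shape (n,)
        Outcome vector. Real-valued for the gaussian family, 0/1 for
        binomial-probit.
    Z : ndarray, shape (n, M)
        Exposure matrix; the columns are the arguments of h.
    X : ndarray, shape (n, P)
        Covariate matrix, P >= 0 (may have zero columns).
    cluster_id : ndarray of int, shape (n,), optional
        Cluster labels, coded 0..(n_clusters - 1).
    family : str
        One of ``FAMILIES``.
    """

    y: np.ndarray
    Z: np.ndarray
    X: np.ndarray
    cluster_id: np.ndarray | None = None
    family: str = "gaussian"
    exposure_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)
    outcome_name: str = "y"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(-1, 1)
        if self.X.size == 0:
            self.X = np.zeros((self.y.shape[0], 0))
        if not self.exposure_names:
            self.exposure_names = [f"z{m + 1}" for m in range(self.M)]
        if not self.covariate_names:
            self.covariate_names = [f"x{p + 1}" for p in range(self.P)]
        self.validate()

    # -- basic dimensions -------------------------------------------------
    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def M(self) -> int:
        return self.Z.shape[1]

    @property
    def P(self) -> int:
        return self.X.shape[1]

    @property
    def n_clusters(self) -> int:
        if self.cluster_id is None:
            return 0
        return int(self.cluster_id.max()) + 1

    def validate(self) -> None:
        n = self.n
        if self.Z.shape[0] != n or self.X.shape[0] != n:
            raise ValueError(
                f"row mismatch: y has {n} rows, Z has {self.Z.shape[0]}, "
                f"X has {self.X.shape[0]}"
            )
        for name, arr in (("y", self.y), ("Z", self.Z), ("X", self.X)):
            if arr.size and not np.all(np.isfinite(arr)):
                bad = np.argwhere(~np.isfinite(np.atleast_2d(arr)))
                raise ValueError(
                    f"missing/non-finite values in {name} at (row, col) {bad[:5].tolist()}"
                )
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.family == "binomial-probit":
            bad = np.setdiff1d(np.unique(self.y), [0.0, 1.0])
            if bad.size:
                raise ValueError(
                    f"binomial-probit outcome must be 0/1; found value(s) {bad.tolist()}"
                )
        if self.cluster_id is not None:
            self.cluster_id = np.asarray(self.cluster_id)
            if self.cluster_id.shape[0] != n:
                raise ValueError("cluster_id length does not match n")
            # recode to consecutive integers 0..C-1
            _, codes = np.unique(self.cluster_id, return_inverse=True)
            self.cluster_id = codes.astype(int)
        if n < self.M + self.P + 2:
            warnings.warn(
                f"n = {n} is small relative to M + P = {self.M + self.P}; "
                "posterior summaries may be unstable",
                UserWarning,
                stacklevel=2,
            )


def validate_dataset(
    table: pd.DataFrame,
    outcome: str,
    exposures: list[str],
    covariates: list[str] | None = None,
    cluster: str | None = None,
    family: str = "gaussian",
) -> MixtureDataset:
    """Validate a parsed CSV table and assemble a :class:`MixtureDataset`.

    Parameters name the column roles; every named column must exist, no value
    may be missing, and no column may serve two roles.
    """
    covariates = list(covariates or [])
    exposures = list(exposures)
    roles = [outcome, *exposures, *covariates] + ([cluster] if cluster else [])
    dup = {c for c in roles if roles.count(c) > 1}
    if dup:
        raise ValueError(f"column(s) {sorted(dup)} assigned to more than one role")
    missing_cols = [c for c in roles if c not in table.columns]
    if missing_cols:
        raise ValueError(f"column(s) {missing_cols} not present in table")

    sub = table[[c for c in roles if c is not None]]
    if sub.isna().any().any():
        na = sub.isna()
        cells = [(int(i), c) for c in na.columns for i in na.index[na[c]][:3]]
        raise ValueError(f"missing values at (row, column): {cells[:10]}")

    return MixtureDataset(
        y=table[outcome].to_numpy(dtype=float),
        Z=table[exposures].to_numpy(dtype=float),
        X=table[covariates].to_numpy(dtype=float)
        if covariates
        else np.zeros((len(table), 0)),
        cluster_id=table[cluster].to_numpy() if cluster else None,
        family=family,
        exposure_names=exposures,
        covariate_names=covariates,
        outcome_name=outcome,
    )


def standardize_exposures(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale each exposure column to mean 0, sample sd 1.

    Standardizing makes the kernel weights r_m comparable across exposures
    measured on different scales. Returns ``(Z_std, centers, scales)``; the
    transform is inverted as ``Z_std * scales + centers``.

    Raises
    ------
    ValueError
        If any column is constant (zero sample standard deviation).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    centers = Z.mean(axis=0)
    scales = Z.std(axis=0, ddof=1)
    const = np.flatnonzero(scales == 0)
    if const.size:
        raise ValueError(f"constant exposure column(s) at index {const.tolist()}")
    return (Z - centers) / scales, centers, scales
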