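"""Marginal-covariance algebra for the kernel machine model.

With the exposure-response surface h integrated out, the response is
multivariate normal with covariance

    Sigma = sigma^2 * C,    C = I + lam * K_r + lam_b * G G',

where K_r is the (possibly low-rank predictive-process) kernel matrix and G
is the cluster indicator matrix. Every sampler block needs solves and
log-determinants with C; this module provides them through two
interchangeable backends:

* :class:`DenseCov` — Cholesky of the dense n x n matrix;
* :class:`WoodburyCov` — for C = I + U U' with a thin U (predictive-process
  factor columns and/or cluster indicators), solves and log-determinants go
  through the (k x k) capacitance matrix I + U'U only, so the cost per
  likelihood evaluation is O(n k^2) rather than O(n^3).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .data import MixtureDataset
from .kernels import (
    LowRankKernel,
    component_sqdists,
    kernel_from_sqdists,
)

__all__ = ["DenseCov", "WoodburyCov", "Workspace", "gaussian_logpdf"]


class DenseCov:
    """Cholesky-backed operator for a dense C = I + lam*K + lam_b*GG'."""

    kind = "dense"

    def __init__(self, C: np.ndarray, lam: float, K: np.ndarray,
                 lam_b: float | None = None):
        self.lam = lam
        self.K = K
        self.lam_b = lam_b
        try:
            self._cf = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            # symmetric-eigenvalue fallback with small-eigenvalue clipping
            w, V = linalg.eigh(C)
            w = np.clip(w, 1e-10, None)
            self._cf = linalg.cho_factor(V @ (w[:, None] * V.T), lower=True)
        self._logdet = 2.0 * float(np.sum(np.log(np.diag(self._cf[0]))))

    def solve(self, B: np.ndarray) -> np.ndarray:
        return linalg.cho_solve(self._cf, B, check_finite=False)

    def quad(self, v: np.ndarray) -> float:
        return float(v @ self.solve(v))

    @property
    def logdet(self) -> float:
        return self._logdet


class WoodburyCov:
    """Low-rank operator for C = I + U U' (predictive-process / cluster terms).

    Solves use the Woodbury identity C^{-1} = I - U (I + U'U)^{-1} U' and the
    matrix-determinant lemma log|C| = log|I + U'U|; only the k x k
    capacitance matrix is ever factorized.
    """

    kind = "lowrank"

    def __init__(self, U: np.ndarray, lam: float,
                 lrk: LowRankKernel | None = None,
                 lam_b: float | None = None):
        self.U = U
        self.lam = lam
        self.lrk = lrk
        self.lam_b = lam_b
        k = U.shape[1]
        cap = np.eye(k) + U.T @ U
        self._cf = linalg.cho_factor(cap, lower=True, check_finite=False)
        self._logdet = 2.0 * float(np.sum(np.log(np.diag(self._cf[0]))))

    def solve(self, B: np.ndarray) -> np.ndarray:
        return B - self.U @ linalg.cho_solve(self._cf, self.U.T @ B,
                                             check_finite=False)

    def quad(self, v: np.ndarray) -> float:
        return float(v @ self.solve(v))

    @property
    def logdet(self) -> float:
        return self._logdet


def gaussian_logpdf(resid: np.ndarray, cov, sigma2: float) -> float:
    """log N(resid | 0, sigma2 * C) for a covariance operator ``cov``."""
    n = resid.shape[0]
    return -0.5 * (
        n * np.log(2.0 * np.pi * sigma2) + cov.logdet + cov.quad(resid) / sigma2
    )


class Workspace:
    """Precomputed geometry for one dataset: squared distances, cluster
    indicators, and the covariance-operator factory used by every MCMC block
    and by posterior prediction."""

    def __init__(self, data: MixtureDataset, knots: np.ndarray | None = None,
                 nugget: float = 1e-6):
        self.data = data
        self.Z = data.Z
        self.X = data.X
        self.y = data.y
        self.knots = None if knots is None else np.atleast_2d(np.asarray(knots, float))
        self.nugget = nugget
        if data.cluster_id is not None:
            C = data.n_clusters
            if C < 2:
                raise ValueError(
                    "clustered model needs at least two clusters; tau_b^2 is "
                    "unidentifiable with a single cluster"
                )
            G = np.zeros((data.n, C))
            G[np.arange(data.n), data.cluster_id] = 1.0
            self.G = G
        else:
            self.G = None
        if self.knots is None:
            self.D = component_sqdists(self.Z, self.Z)  # (M, n, n)
        else:
            if self.knots.shape[1] != data.M:
                raise ValueError("knots must have M columns")
            self.Dzu = component_sqdists(self.Z, self.knots)
            self.Duu = component_sqdists(self.knots, self.knots)

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def clustered(self) -> bool:
        return self.G is not None

    def _lowrank(self, r: np.ndarray) -> LowRankKernel:
        K_uu = kernel_from_sqdists(self.Duu, r)
        K_uu[np.diag_indices_from(K_uu)] += self.nugget
        L = linalg.cholesky(K_uu, lower=True)
        K_zu = kernel_from_sqdists(self.Dzu, r)
        A = linalg.solve_triangular(L, K_zu.T, lower=True).T
        return LowRankKernel(A=A, knots=self.knots, chol_knots=L,
                             r=np.asarray(r, float), nugget=self.nugget)

    def cov(self, lam: float, r: np.ndarray, lam_b: float | None = None):
        """Covariance operator for C = I + lam*K_r (+ lam_b*GG')."""
        if self.knots is None:
            K = kernel_from_sqdists(self.D, r)
            C = lam * K
            if self.clustered:
                C += lam_b * (self.G @ self.G.T)
            C[np.diag_indices_from(C)] += 1.0
            return DenseCov(C, lam=lam, K=K, lam_b=lam_b)
        lrk = self._lowrank(r)
        parts = [np.sqrt(lam) * lrk.A]
        if self.clustered:
            parts.append(np.sqrt(lam_b) * self.G)
        U = np.hstack(parts)
        return WoodburyCov(U, lam=lam, lrk=lrk, lam_b=lam_b)

    def cov_from_kernel(self, K: np.ndarray, lam: float,
                        lam_b: float | None = None) -> DenseCov:
        """Dense covariance operator from an already-built kernel matrix
        (single-component proposals update K multiplicatively)."""
        C = lam * K
        if self.clustered:
            C += lam_b * (self.G @ self.G.T)
        C[np.diag_indices_from(C)] += 1.0
        return DenseCov(C, lam=lam, K=K, lam_b=lam_b)

    def loglik(self, cov, resp: np.ndarray, beta: np.ndarray, sigma2: float) -> float:
        resid = resp - self.X @ beta if self.X.shape[1] else resp
        return gaussian_logpdf(resid, cov, sigma2)
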