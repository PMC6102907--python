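"""Component-weighted Gaussian kernel, knot selection, and the low-rank
Gaussian-predictive-process machinery.

The kernel is K(z, z') = exp{-sum_m r_m (z_m - z'_m)^2} with nonnegative
weights r_m; a weight of zero removes exposure m from the distance, which is
how spike-and-slab selection excludes an exposure from the surface. Distances
use the unscaled sum convention (no division by M).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.cluster import KMeans

__all__ = [
    "gaussian_kernel_matrix",
    "component_sqdists",
    "kernel_from_sqdists",
    "select_knots",
    "LowRankKernel",
    "low_rank_kernel",
]

DEFAULT_NUGGET = 1e-6


def _check_r(r: np.ndarray, M: int) -> np.ndarray:
    r = np.asarray(r, dtype=float).ravel()
    if r.shape[0] != M:
        raise ValueError(f"r has length {r.shape[0]} but Z has {M} columns")
    if np.any(r < 0):
        raise ValueError("kernel weights r must be nonnegative")
    return r


def component_sqdists(Z1: np.ndarray, Z2: np.ndarray) -> np.ndarray:
    """Per-exposure squared distances, shape (M, n1, n2).

    Cached by the sampler so that re-weighting by r is a tensordot, not a
    re-computation of pairwise differences.
    """
    Z1 = np.atleast_2d(np.asarray(Z1, dtype=float))
    Z2 = np.atleast_2d(np.asarray(Z2, dtype=float))
    if Z1.shape[1] != Z2.shape[1]:
        raise ValueError("Z1 and Z2 must have the same number of columns")
    diff = Z1[:, None, :] - Z2[None, :, :]  # (n1, n2, M)
    return np.ascontiguousarray(np.moveaxis(diff**2, -1, 0))


def kernel_from_sqdists(D: np.ndarray, r: np.ndarray) -> np.ndarray:
    r = _check_r(r, D.shape[0])
    return np.exp(-np.tensordot(r, D, axes=1))


def gaussian_kernel_matrix(Z1: np.ndarray, Z2: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Gaussian kernel matrix K[i, j] = exp{-sum_m r_m (Z1[i,m] - Z2[j,m])^2}."""
    Z1 = np.atleast_2d(np.asarray(Z1, dtype=float))
    Z2 = np.atleast_2d(np.asarray(Z2, dtype=float))
    if Z1.shape[1] != Z2.shape[1]:
        raise ValueError("Z1 and Z2 must have the same number of columns")
    r = _check_r(r, Z1.shape[1])
    # (z - z')^2 expansion avoids the (n1, n2, M) intermediate
    W1 = Z1 * np.sqrt(r)
    W2 = Z2 * np.sqrt(r)
    sq = (
        (W1**2).sum(axis=1)[:, None]
        + (W2**2).sum(axis=1)[None, :]
        - 2.0 * W1 @ W2.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq)


def select_knots(
    Z: np.ndarray,
    n_knots: int,
    method: str = "kmeans",
    seed: int | None = None,
) -> np.ndarray:
    """Pick a set of knots covering the exposure space.

    ``kmeans`` uses cluster centroids (a reproducible space-covering choice);
    ``random-subset`` samples distinct rows of Z without replacement.
    Deterministic given ``seed``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[0]
    if not 1 <= n_knots <= n:
        raise ValueError(f"n_knots must be in [1, {n}], got {n_knots}")
    if method == "kmeans":
        if n_knots == n:
            return Z.copy()
        km = KMeans(n_clusters=n_knots, n_init=10, random_state=seed)
        km.fit(Z)
        centers = km.cluster_centers_
        # clip to the bounding box of Z (centroids are convex combinations,
        # so this is a no-op guard against floating error)
        return np.clip(centers, Z.min(axis=0), Z.max(axis=0))
    if method == "random-subset":
        Zu = np.unique(Z, axis=0)
        if n_knots >= Zu.shape[0]:
            return Zu
        rng = np.random.default_rng(seed)
        idx = rng.choice(Zu.shape[0], size=n_knots, replace=False)
        return Zu[np.sort(idx)]
    raise ValueError(f"unknown knot method {method!r}")


@dataclass
class LowRankKernel:
    """Factorization of the predictive-process kernel.

    Kt = K_{Z,u} (K_{u,u} + nugget I)^{-1} K_{u,Z} = A A' with
    A = K_{Z,u} L^{-T}, where L is the lower Cholesky factor of
    K_{u,u} + nugget I and u is the knot set. Likelihood algebra built on A
    only ever factorizes matrices of knot dimension.
    """

    A: np.ndarray  # (n, K)
    knots: np.ndarray  # (K, M)
    chol_knots: np.ndarray  # lower Cholesky of K_uu + nugget I
    r: np.ndarray
    nugget: float

    def matrix(self) -> np.ndarray:
        """Dense n x n approximate kernel matrix (symmetric PSD)."""
        return self.A @ self.A.T

    def cross_factor(self, Z_new: np.ndarray) -> np.ndarray:
        """Factor A_new with Kt(Z_new, Z) = A_new @ A.T."""
        K_nu = gaussian_kernel_matrix(Z_new, self.knots, self.r)
        return linalg.solve_triangular(self.chol_knots, K_nu.T, lower=True).T


def low_rank_kernel(
    Z: np.ndarray,
    knots: np.ndarray,
    r: np.ndarray,
    nugget: float = DEFAULT_NUGGET,
) -> LowRankKernel:
    """Build the Gaussian-predictive-process factorization for Z and knots."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    knots = np.atleast_2d(np.asarray(knots, dtype=float))
    if knots.shape[0] == 0:
        raise ValueError("knot set must be nonempty")
    if knots.shape[1] != Z.shape[1]:
        raise ValueError("knots must have the same number of columns as Z")
    if not 0 < nugget <= 1e-4:
        raise ValueError("nugget must lie in (0, 1e-4]")
    r = _check_r(r, Z.shape[1])
    K_uu = gaussian_kernel_matrix(knots, knots, r)
    K_uu[np.diag_indices_from(K_uu)] += nugget
    try:
        L = linalg.cholesky(K_uu, lower=True)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "knot kernel matrix is singular even after adding the nugget; "
            "use fewer knots or remove duplicate knot rows"
        ) from err
    K_zu = gaussian_kernel_matrix(Z, knots, r)
    A = linalg.solve_triangular(L, K_zu.T, lower=True).T
    return LowRankKernel(A=A, knots=knots, chol_knots=L, r=r, nugget=nugget)
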