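"""Synthetic mixture datasets with known exposure-response truth.

Two default scenarios mirror the structure of typical multi-pollutant
benchmark studies, with the true surface exposed so that estimator output
can be scored against it:

* ``simulate_continuous`` — n = 500 individuals, M = 7 correlated exposures
  (exchangeable rho = 0.3), one covariate; the true surface combines a
  saturating (plateau) dose-response term, linear terms of both signs, and a
  product interaction, with exposures z3 and z6 inert.
* ``simulate_binary`` — n = 200, M = 30 independent exposures; the binary
  outcome arises by thresholding a latent normal whose mean depends on
  centered quadratic terms of exposures z1-z4 and a linear z1*z2
  interaction.
* ``simulate_clustered`` — the continuous scenario plus a cluster random
  intercept b_i ~ N(0, tau_b^2).

The surface library (linear / quadratic / plateau / product terms) is
composable, and every generator is a pure function of its spec, seed
included. Truth records evaluate h_true anywhere and compute every
population contrast (overall, single-exposure, interactive, probit risk
differences) in closed form at the empirical exposure quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import MixtureDataset

__all__ = [
    "GenerativeSpec",
    "TruthRecord",
    "exchangeable_corr",
    "make_h",
    "simulate_continuous",
    "simulate_binary",
    "simulate_clustered",
    "true_contrasts",
    "CONTINUOUS_TERMS",
    "BINARY_TERMS",
]

# term grammar: ("linear", m, a) -> a * z_m
#               ("quadratic", m, a) -> a * (z_m^2 - 1)   (centered for N(0,1))
#               ("plateau", m, a, rate) -> a / (1 + exp(-rate * z_m))
#               ("product", m1, m2, c) -> c * z_m1 * z_m2
CONTINUOUS_TERMS: tuple = (
    ("plateau", 6, 1.8, 2.0),
    ("linear", 0, 0.5),
    ("linear", 1, 0.4),
    ("linear", 3, -0.4),
    ("linear", 4, -0.5),
    ("product", 0, 4, -0.3),
)

BINARY_TERMS: tuple = (
    ("quadratic", 0, 0.8),
    ("quadratic", 1, 0.8),
    ("quadratic", 2, 0.6),
    ("quadratic", 3, 0.6),
    ("product", 0, 1, 0.5),
)


def make_h(terms: Sequence[tuple]) -> Callable[[np.ndarray], np.ndarray]:
    """Compile a term list into a vectorized h(Z) evaluable at (k, M) arrays."""

    def h(Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        out = np.zeros(Z.shape[0])
        for term in terms:
            kind = term[0]
            if kind == "linear":
                _, m, a = term
                out += a * Z[:, m]
            elif kind == "quadratic":
                _, m, a = term
                out += a * (Z[:, m] ** 2 - 1.0)
            elif kind == "plateau":
                _, m, a, rate = term
                out += a / (1.0 + np.exp(-rate * Z[:, m]))
            elif kind == "product":
                _, m1, m2, c = term
                out += c * Z[:, m1] * Z[:, m2]
            else:
                raise ValueError(f"unknown term kind {kind!r}")
        return out

    return h


def _active_set(terms: Sequence[tuple]) -> set[int]:
    act: set[int] = set()
    for term in terms:
        if term[0] == "product":
            act.update(term[1:3])
        else:
            act.add(term[1])
    return act


def exchangeable_corr(
    M: int, rho: float = 0.3, pairs: Sequence[tuple[int, int, float]] = ()
) -> np.ndarray:
    """Exchangeable correlation matrix, optionally with extra high-correlation
    pairs (for hierarchical-selection demonstrations)."""
    R = np.full((M, M), rho)
    np.fill_diagonal(R, 1.0)
    for i, j, rij in pairs:
        R[i, j] = R[j, i] = rij
    return R


@dataclass
class GenerativeSpec:
    """Full description of one synthetic scenario; seed is mandatory."""

    n: int
    M: int
    seed: int
    rho: float = 0.3
    corr: np.ndarray | None = None  # overrides rho when given
    terms: Sequence[tuple] = ()
    beta_x: float = 0.5
    noise_sd: float = 0.5  # gaussian family; probit latent noise is fixed at 1
    family: str = "gaussian"
    cluster_sizes: Sequence[int] | None = None
    tau_b: float = 0.0

    def correlation(self) -> np.ndarray:
        R = self.corr if self.corr is not None else exchangeable_corr(self.M, self.rho)
        R = np.asarray(R, dtype=float)
        eig = np.linalg.eigvalsh(R)
        if eig.min() <= 0:
            raise ValueError("exposure correlation matrix is not positive definite")
        return R


@dataclass
class TruthRecord:
    """Everything needed to score an estimate against the generative truth."""

    spec: GenerativeSpec
    h: Callable[[np.ndarray], np.ndarray]
    Z: np.ndarray
    x: np.ndarray
    active: set[int] = field(default_factory=set)
    b: np.ndarray | None = None  # realized cluster intercepts

    def quantile_vector(self, q: float) -> np.ndarray:
        return np.quantile(self.Z, q, axis=0)

    # -- population contrasts under h_true --------------------------------
    def overall_effect(self, q1: float = 0.25, q2: float = 0.75) -> float:
        return float(
            self.h(self.quantile_vector(q2)[None, :])[0]
            - self.h(self.quantile_vector(q1)[None, :])[0]
        )

    def single_exposure_effect(
        self, m: int, q_fix: float = 0.5, q1: float = 0.25, q2: float = 0.75
    ) -> float:
        base = self.quantile_vector(q_fix)
        hi = base.copy()
        hi[m] = self.quantile_vector(q2)[m]
        lo = base.copy()
        lo[m] = self.quantile_vector(q1)[m]
        return float(self.h(hi[None, :])[0] - self.h(lo[None, :])[0])

    def interactive_effect(self, m: int, q1: float = 0.25, q2: float = 0.75) -> float:
        return self.single_exposure_effect(m, q2, q1, q2) - \
            self.single_exposure_effect(m, q1, q1, q2)

    def event_probability(self, z: np.ndarray, x: float) -> float:
        """Exact P(Y=1 | z, x) for the probit truth."""
        if self.spec.family != "binomial-probit":
            raise ValueError("event probabilities require the probit family")
        lin = self.h(np.atleast_2d(z))[0] + self.spec.beta_x * x
        return float(stats.norm.cdf(lin))

    def risk_difference(
        self, m: int = 1, q_hi: float = 0.75, q_lo: float = 0.50,
        x_quantile: float = 0.5,
    ) -> float:
        """True risk difference moving exposure m between two quantiles,
        the rest at their medians, at a covariate quantile."""
        base = self.quantile_vector(0.5)
        za = base.copy()
        za[m] = self.quantile_vector(q_hi)[m]
        zb = base.copy()
        zb[m] = self.quantile_vector(q_lo)[m]
        xv = float(np.quantile(self.x, x_quantile))
        return self.event_probability(za, xv) - self.event_probability(zb, xv)


def _draw_common(spec: GenerativeSpec, rng: np.random.Generator):
    R = spec.correlation()
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((spec.n, spec.M)) @ L.T
    x = rng.standard_normal(spec.n)
    eps = rng.standard_normal(spec.n)
    return Z, x, eps


def simulate_continuous(
    spec: GenerativeSpec | None = None, **overrides
) -> tuple[MixtureDataset, TruthRecord]:
    """Continuous-outcome scenario: y = h_true(Z) + beta_x * x + N(0, sd^2)."""
    if spec is None:
        spec = GenerativeSpec(n=500, M=7, seed=0, terms=CONTINUOUS_TERMS)
    if overrides:
        spec = replace(spec, **overrides)
    rng = np.random.default_rng(spec.seed)
    Z, x, eps = _draw_common(spec, rng)
    h = make_h(spec.terms)
    y = h(Z) + spec.beta_x * x + spec.noise_sd * eps
    data = MixtureDataset(y=y, Z=Z, X=x[:, None], family="gaussian")
    truth = TruthRecord(spec=spec, h=h, Z=Z, x=x, active=_active_set(spec.terms))
    return data, truth


def simulate_binary(
    spec: GenerativeSpec | None = None, **overrides
) -> tuple[MixtureDataset, TruthRecord]:
    """Probit scenario: y = 1{h_true(Z) + beta_x * x + N(0,1) > 0}."""
    if spec is None:
        spec = GenerativeSpec(
            n=200, M=30, seed=0, rho=0.0, terms=BINARY_TERMS, beta_x=0.3,
            family="binomial-probit",
        )
    if overrides:
        spec = replace(spec, **overrides)
    spec = replace(spec, family="binomial-probit")
    rng = np.random.default_rng(spec.seed)
    Z, x, eps = _draw_common(spec, rng)
    h = make_h(spec.terms)
    y_star = h(Z) + spec.beta_x * x + eps
    y = (y_star > 0).astype(float)
    prev = y.mean()
    if prev == 0.0 or prev == 1.0:
        raise ValueError(
            f"degenerate binary outcome (prevalence {prev:.0%}); "
            "rescale the surface coefficients or the covariate effect"
        )
    data = MixtureDataset(y=y, Z=Z, X=x[:, None], family="binomial-probit")
    truth = TruthRecord(spec=spec, h=h, Z=Z, x=x, active=_active_set(spec.terms))
    return data, truth


def simulate_clustered(
    spec: GenerativeSpec | None = None, **overrides
) -> tuple[MixtureDataset, TruthRecord]:
    """Clustered continuous scenario: adds b_i ~ N(0, tau_b^2) per cluster.

    ``cluster_sizes`` partitions the n observations; with tau_b = 0 the
    outcome equals the unclustered generator's for the same seed.
    """
    if spec is None:
        spec = GenerativeSpec(
            n=200, M=7, seed=0, terms=CONTINUOUS_TERMS,
            cluster_sizes=[20] * 10, tau_b=0.5,
        )
    if overrides:
        spec = replace(spec, **overrides)
    sizes = list(spec.cluster_sizes or [])
    if len(sizes) < 2 or any(s < 1 for s in sizes):
        raise ValueError("need at least 2 clusters with at least 1 member each")
    if sum(sizes) != spec.n:
        raise ValueError(f"cluster sizes sum to {sum(sizes)}, expected n = {spec.n}")
    rng = np.random.default_rng(spec.seed)
    Z, x, eps = _draw_common(spec, rng)
    b_raw = rng.standard_normal(len(sizes))
    b = spec.tau_b * b_raw
    cluster_id = np.repeat(np.arange(len(sizes)), sizes)
    h = make_h(spec.terms)
    y = h(Z) + spec.beta_x * x + b[cluster_id] + spec.noise_sd * eps
    data = MixtureDataset(
        y=y, Z=Z, X=x[:, None], cluster_id=cluster_id, family="gaussian"
    )
    truth = TruthRecord(
        spec=spec, h=h, Z=Z, x=x, active=_active_set(spec.terms), b=b
    )
    return data, truth


def true_contrasts(
    truth: TruthRecord,
    q_pair: tuple[float, float] = (0.25, 0.75),
    fix_quantile: float = 0.5,
    rd_exposure: int = 1,
    rd_quantiles: tuple[float, float] = (0.75, 0.50),
    rd_x_quantiles: tuple[float, ...] = (0.25, 0.75),
) -> pd.DataFrame:
    """Table of every true estimand under h_true at the empirical quantiles.

    For probit truths the table additionally holds exact risk differences
    for ``rd_exposure`` moved between ``rd_quantiles`` (others at medians)
    at each covariate quantile in ``rd_x_quantiles``.
    """
    q1, q2 = q_pair
    rows = [
        {"name": f"overall({q1:g},{q2:g})",
         "truth": truth.overall_effect(q1, q2)}
    ]
    for m in range(truth.spec.M):
        rows.append(
            {"name": f"single[z{m + 1}|{fix_quantile:g}]",
             "truth": truth.single_exposure_effect(m, fix_quantile, q1, q2)}
        )
    for m in range(truth.spec.M):
        rows.append(
            {"name": f"interact[z{m + 1}]",
             "truth": truth.interactive_effect(m, q1, q2)}
        )
    if truth.spec.family == "binomial-probit":
        for xq in rd_x_quantiles:
            rows.append(
                {"name": f"risk_difference[x@{xq:g}]",
                 "truth": truth.risk_difference(
                     rd_exposure, rd_quantiles[0], rd_quantiles[1], xq)}
            )
    return pd.DataFrame(rows)
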