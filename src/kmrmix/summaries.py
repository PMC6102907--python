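"""Post-processing of a fitted model: surface prediction, inclusion
probabilities, cross-sections, and effect contrasts.

All estimands are functionals of the exposure-response surface h evaluated
at exposure profiles built from empirical quantiles (linear-interpolation
convention) of the training exposures:

* overall effect      Delta_tot(q1, q2) = h(z^{q2}) - h(z^{q1}), every
  exposure moved jointly between quantiles, covariates held constant;
* single-exposure     Delta_m(q1, q2 | q) moves only exposure m with the
  others fixed at their q-quantile;
* interactive effect  Delta_m(25, 75 | 75) - Delta_m(25, 75 | 25), nonzero
  when the effect of exposure m depends on co-exposure levels;
* probit scale        event probabilities Phi(h + x'beta) and risk
  differences between two exposure settings.

Contrasts are computed draw-wise: for each stored MCMC state the joint
Gaussian conditional of h at all required points is drawn once (common
random draw), so contrast uncertainty reflects the posterior covariance of
the surface rather than independent prediction noise. Draws are seeded
deterministically from the stored chain seed and the prediction points, so
recomputation from persisted samples is bit-for-bit reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import gaussian_kernel_matrix
from .mcmc import _draw_mvn
from .samples import PosteriorSamples

__all__ = [
    "HPrediction",
    "EffectSummary",
    "extract_pips",
    "predict_h",
    "h_conditional_moments",
    "single_exposure_draws",
    "univariate_cross_section",
    "bivariate_cross_section",
    "overall_effect",
    "single_exposure_effects",
    "interactive_effects",
    "predict_probability",
    "risk_difference",
    "probit_to_logit",
    "saturated_model_parameter_count",
]


@dataclass
class HPrediction:
    """Posterior draws of h at a set of exposure profiles.

    ``draws`` has one row per stored MCMC state and one column per point.
    ``mode`` records whether rows are conditional draws ("full-posterior")
    or per-state conditional means ("mean-only") — interval widths differ
    between the two. ``scale`` is "latent" for probit fits.
    """

    points: np.ndarray
    draws: np.ndarray
    mode: str
    scale: str

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)

    def interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        a = (1.0 - level) / 2.0
        return (
            np.quantile(self.draws, a, axis=0),
            np.quantile(self.draws, 1.0 - a, axis=0),
        )


@dataclass
class EffectSummary:
    """Posterior mean and equal-tailed 95% interval of a named h contrast."""

    name: str
    setting_a: np.ndarray
    setting_b: np.ndarray
    mean: float
    sd: float
    lower: float
    upper: float


def _summarize(name, a, b, draws, **extra) -> dict:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {
        "name": name,
        **extra,
        "mean": float(np.mean(draws)),
        "sd": float(np.std(draws, ddof=1)),
        "lower": float(lo),
        "upper": float(hi),
    }


# ---------------------------------------------------------------------------
# inclusion probabilities
# ---------------------------------------------------------------------------

def extract_pips(samples: PosteriorSamples, groups=None) -> pd.DataFrame:
    """Posterior inclusion probabilities.

    Component-wise selection returns one row per exposure with
    ``pip = mean(delta_m)``. Hierarchical selection returns, per grouped
    exposure, the group PIP (posterior frequency that any member of the
    group is active) and the conditional within-group PIP (frequency the
    member is the active one, given the group is active); conditional PIPs
    sum to 1 within a group.
    """
    if not samples.varsel:
        raise ValueError(
            "PIPs are undefined without variable selection (varsel was off)"
        )
    groups = groups if groups is not None else samples.groups
    names = samples.data.exposure_names
    delta = samples.delta
    if groups is None or not groups.groups:
        return pd.DataFrame(
            {"exposure": names, "pip": delta.mean(axis=0)}
        )
    rows = []
    for label, members in groups.groups.items():
        any_active = delta[:, list(members)].max(axis=1)
        gp = float(any_active.mean())
        n_active = int(any_active.sum())
        for m in members:
            cond = float(delta[any_active == 1, m].mean()) if n_active else np.nan
            rows.append(
                {"exposure": names[m], "group": label,
                 "group_pip": gp, "cond_pip": cond}
            )
    for m in groups.ungrouped(samples.M):
        rows.append(
            {"exposure": names[m], "group": None,
             "group_pip": float(delta[:, m].mean()), "cond_pip": 1.0}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# surface prediction
# ---------------------------------------------------------------------------

def _standardize_points(samples: PosteriorSamples, Z_new: np.ndarray) -> np.ndarray:
    Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
    if Z_new.shape[1] != samples.M:
        raise ValueError(
            f"prediction points have {Z_new.shape[1]} columns, expected {samples.M}"
        )
    return (Z_new - samples.centers) / samples.scales


def _derived_rng(samples: PosteriorSamples, Z_new: np.ndarray) -> np.random.Generator:
    crc = zlib.crc32(np.ascontiguousarray(Z_new, dtype=float).tobytes())
    return np.random.default_rng([samples.seed % (2**31), crc])


def _state_h_moments(samples, ws, s, Zs, want_cov):
    """Conditional mean (and covariance) of h(Zs) under stored state s.

    mean = lam K_{new,n} C^{-1} (resp - X beta)
    cov  = sigma^2 [lam K_{new,new} - lam^2 K_{new,n} C^{-1} K_{n,new}]
    with C = I + lam K (+ lam_b GG'); predictive-process mode substitutes the
    low-rank factors throughout.
    """
    lam = float(samples.lam[s])
    r = samples.r[s]
    s2 = float(samples.sigma2[s])
    k = Zs.shape[0]
    if lam == 0.0:
        return np.zeros(k), (np.zeros((k, k)) if want_cov else None)
    cov = ws.cov(lam, r, samples.lam_b(s))
    resp = samples.response(s)
    resid = resp - ws.X @ samples.beta[s] if ws.X.shape[1] else resp
    alpha = cov.solve(resid)
    if cov.kind == "dense":
        Kcross = gaussian_kernel_matrix(Zs, ws.Z, r)
        mean = lam * (Kcross @ alpha)
        if not want_cov:
            return mean, None
        Knew = gaussian_kernel_matrix(Zs, Zs, r)
        covh = s2 * (lam * Knew - lam**2 * (Kcross @ cov.solve(Kcross.T)))
        return mean, covh
    lrk = cov.lrk
    A_new = lrk.cross_factor(Zs)
    mean = lam * (A_new @ (lrk.A.T @ alpha))
    if not want_cov:
        return mean, None
    CiA = cov.solve(lrk.A)
    S = s2 * (lam * np.eye(lrk.A.shape[1]) - lam**2 * (lrk.A.T @ CiA))
    return mean, A_new @ S @ A_new.T


def h_conditional_moments(
    samples: PosteriorSamples, state_index: int, Z_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional mean and covariance of h(Z_new) for one stored state."""
    Zs = _standardize_points(samples, Z_new)
    return _state_h_moments(samples, samples.workspace(), state_index, Zs, True)


def predict_h(
    samples: PosteriorSamples,
    Z_new: np.ndarray,
    mode: str = "full-posterior",
    rng: np.random.Generator | None = None,
) -> HPrediction:
    """Posterior draws (or per-state conditional means) of h at new points.

    ``Z_new`` is on the original exposure scale and is standardized with the
    training constants. In "full-posterior" mode one joint conditional draw
    per stored state is taken across all points (duplicated rows receive
    identical values); "mean-only" skips the conditional noise and is the
    fast choice for plots and posterior-mean surfaces.
    """
    if mode not in ("full-posterior", "mean-only"):
        raise ValueError(f"unknown mode {mode!r}")
    Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
    Zs_all = _standardize_points(samples, Z_new)
    if rng is None:
        rng = _derived_rng(samples, Zs_all)
    uniq, inv = np.unique(Zs_all, axis=0, return_inverse=True)
    ws = samples.workspace()
    S = samples.n_states
    out = np.empty((S, uniq.shape[0]))
    want_cov = mode == "full-posterior"
    for s in range(S):
        mean, covh = _state_h_moments(samples, ws, s, uniq, want_cov)
        out[s] = _draw_mvn(rng, mean, covh) if want_cov else mean
    scale = "latent" if samples.family == "binomial-probit" else "response"
    return HPrediction(points=Z_new, draws=out[:, inv], mode=mode, scale=scale)


# ---------------------------------------------------------------------------
# quantile profiles and effect contrasts
# ---------------------------------------------------------------------------

def _quantile_vector(samples: PosteriorSamples, q: float) -> np.ndarray:
    """Per-exposure empirical q-quantile on the original scale."""
    if not 0 < q < 1:
        raise ValueError(f"quantile must lie in (0, 1), got {q}")
    return np.quantile(samples.Z_orig, q, axis=0)


def overall_effect(
    samples: PosteriorSamples,
    quantile_pairs=((0.25, 0.75),),
    mode: str = "full-posterior",
) -> pd.DataFrame:
    """Overall mixture effect Delta_tot(q1, q2) for each quantile pair.

    All exposures move jointly from their q1- to their q2-quantile profile;
    covariates never enter. The default pair contrasts the 75th against the
    25th percentile profile.
    """
    rows = []
    for q1, q2 in quantile_pairs:
        a = _quantile_vector(samples, q2)
        b = _quantile_vector(samples, q1)
        pred = predict_h(samples, np.vstack([a, b]), mode=mode)
        draws = pred.draws[:, 0] - pred.draws[:, 1]
        rows.append(
            _summarize(f"overall({q1:g},{q2:g})", a, b, draws, q1=q1, q2=q2)
        )
    return pd.DataFrame(rows)


def single_exposure_draws(
    samples: PosteriorSamples,
    fix_quantile: float,
    q_pair: tuple[float, float] = (0.25, 0.75),
    mode: str = "full-posterior",
) -> np.ndarray:
    """Draws of Delta_m(q1, q2 | fix_quantile) for every exposure, shape (S, M).

    All 2M contrast points for one conditioning quantile are drawn jointly
    per state, so differences of these draw matrices across conditioning
    quantiles are the draw-wise interactive effects.
    """
    q1, q2 = q_pair
    base = _quantile_vector(samples, fix_quantile)
    lo = _quantile_vector(samples, q1)
    hi = _quantile_vector(samples, q2)
    M = samples.M
    pts = np.empty((2 * M, M))
    for m in range(M):
        pts[2 * m] = base
        pts[2 * m, m] = hi[m]
        pts[2 * m + 1] = base
        pts[2 * m + 1, m] = lo[m]
    pred = predict_h(samples, pts, mode=mode)
    return pred.draws[:, 0::2] - pred.draws[:, 1::2]


def single_exposure_effects(
    samples: PosteriorSamples,
    fix_quantiles=(0.25, 0.50, 0.75),
    q_pair: tuple[float, float] = (0.25, 0.75),
    mode: str = "full-posterior",
) -> pd.DataFrame:
    """Delta_m(q1, q2 | q) for every exposure m and conditioning quantile q."""
    names = samples.data.exposure_names
    rows = []
    for q in fix_quantiles:
        draws = single_exposure_draws(samples, q, q_pair=q_pair, mode=mode)
        for m in range(samples.M):
            rows.append(
                _summarize(
                    f"single[{names[m]}|{q:g}]", None, None, draws[:, m],
                    exposure=names[m], fix_quantile=q,
                )
            )
    return pd.DataFrame(rows)


def interactive_effects(
    samples: PosteriorSamples,
    q_pair: tuple[float, float] = (0.25, 0.75),
    mode: str = "full-posterior",
) -> pd.DataFrame:
    """Interactive effect Delta_m(25,75|75) - Delta_m(25,75|25) per exposure.

    Computed as the draw-wise difference of the two conditional
    single-exposure contrast draws, so the identity with
    :func:`single_exposure_draws` holds state by state.
    """
    q_lo, q_hi = q_pair
    d_hi = single_exposure_draws(samples, q_hi, q_pair=q_pair, mode=mode)
    d_lo = single_exposure_draws(samples, q_lo, q_pair=q_pair, mode=mode)
    names = samples.data.exposure_names
    rows = [
        _summarize(
            f"interact[{names[m]}]", None, None, d_hi[:, m] - d_lo[:, m],
            exposure=names[m],
        )
        for m in range(samples.M)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-sections
# ---------------------------------------------------------------------------

def _check_grid_range(samples, m, grid):
    zcol = samples.Z_orig[:, m]
    if np.min(grid) < zcol.min() or np.max(grid) > zcol.max():
        warnings.warn(
            f"grid for exposure {samples.data.exposure_names[m]} extends "
            "beyond the observed range: extrapolating",
            UserWarning,
            stacklevel=3,
        )


def univariate_cross_section(
    samples: PosteriorSamples,
    m: int,
    grid: np.ndarray | None = None,
    fix_quantile: float = 0.5,
    n_grid: int = 50,
    mode: str = "full-posterior",
) -> pd.DataFrame:
    """Exposure-response curve of one exposure with the others fixed at
    their ``fix_quantile`` (default median) profile; pointwise 95% bands."""
    zcol = samples.Z_orig[:, m]
    if grid is None:
        grid = np.linspace(zcol.min(), zcol.max(), n_grid)
    grid = np.atleast_1d(np.asarray(grid, float))
    _check_grid_range(samples, m, grid)
    base = _quantile_vector(samples, fix_quantile)
    pts = np.tile(base, (grid.shape[0], 1))
    pts[:, m] = grid
    pred = predict_h(samples, pts, mode=mode)
    lo, hi = pred.interval()
    return pd.DataFrame(
        {
            "exposure": samples.data.exposure_names[m],
            "z": grid,
            "mean": pred.mean(),
            "lower": lo,
            "upper": hi,
        }
    )


def bivariate_cross_section(
    samples: PosteriorSamples,
    m1: int,
    m2: int,
    grids: tuple[np.ndarray, np.ndarray] | None = None,
    m3: int | None = None,
    m3_quantiles=(0.10, 0.50, 0.90),
    n_grid: int = 10,
    mode: str = "mean-only",
) -> pd.DataFrame:
    """Predicted-mean surface over two exposures, one panel per quantile of a
    third exposure (remaining exposures at their medians). Panel-to-panel
    variation beyond a constant shift indicates three-way interaction."""
    idx = [m1, m2] + ([m3] if m3 is not None else [])
    if len(set(idx)) != len(idx):
        raise ValueError("exposure indices m1, m2, m3 must be distinct")
    Zo = samples.Z_orig
    if grids is None:
        grids = (
            np.linspace(Zo[:, m1].min(), Zo[:, m1].max(), n_grid),
            np.linspace(Zo[:, m2].min(), Zo[:, m2].max(), n_grid),
        )
    g1, g2 = (np.atleast_1d(np.asarray(g, float)) for g in grids)
    base = _quantile_vector(samples, 0.5)
    frames = []
    panels = m3_quantiles if m3 is not None else (None,)
    for q3 in panels:
        prof = base.copy()
        if m3 is not None:
            prof[m3] = np.quantile(Zo[:, m3], q3)
        G1, G2 = np.meshgrid(g1, g2, indexing="ij")
        pts = np.tile(prof, (G1.size, 1))
        pts[:, m1] = G1.ravel()
        pts[:, m2] = G2.ravel()
        pred = predict_h(samples, pts, mode=mode)
        frames.append(
            pd.DataFrame(
                {
                    "q3": q3,
                    "z1": G1.ravel(),
                    "z2": G2.ravel(),
                    "mean": pred.mean(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# probit scale
# ---------------------------------------------------------------------------

def _require_probit(samples: PosteriorSamples) -> None:
    if samples.family != "binomial-probit":
        raise ValueError(
            "probability-scale summaries require a binomial-probit fit"
        )


def predict_probability(
    samples: PosteriorSamples,
    Z_new: np.ndarray,
    x_new: np.ndarray | None = None,
    mode: str = "full-posterior",
) -> np.ndarray:
    """Posterior draws of P(Y=1) = Phi(h(z) + x'beta), shape (S, n_points)."""
    _require_probit(samples)
    pred = predict_h(samples, Z_new, mode=mode)
    k = pred.draws.shape[1]
    lin = pred.draws
    if samples.beta.shape[1]:
        if x_new is None:
            raise ValueError("x_new is required when the fit has covariates")
        x_new = np.asarray(x_new, dtype=float)
        if x_new.ndim == 1:
            x_new = np.tile(x_new, (k, 1))
        lin = lin + samples.beta @ x_new.T
    return stats.norm.cdf(lin)


def risk_difference(
    samples: PosteriorSamples,
    z_a: np.ndarray,
    z_b: np.ndarray,
    x_settings: np.ndarray | None = None,
) -> pd.DataFrame:
    """Posterior summary of P(Y=1 | z_a, x) - P(Y=1 | z_b, x).

    ``x_settings`` is a (k, P) array of covariate settings (one summary row
    each); h is drawn jointly at the two exposure settings once per state
    and reused across covariate settings.
    """
    _require_probit(samples)
    pts = np.vstack([np.asarray(z_a, float), np.asarray(z_b, float)])
    pred = predict_h(samples, pts, mode="full-posterior")
    P = samples.beta.shape[1]
    if x_settings is None:
        x_settings = np.zeros((1, P))
    x_settings = np.atleast_2d(np.asarray(x_settings, float))
    rows = []
    for x in x_settings:
        shift = samples.beta @ x if P else 0.0
        pa = stats.norm.cdf(pred.draws[:, 0] + shift)
        pb = stats.norm.cdf(pred.draws[:, 1] + shift)
        rows.append(
            _summarize("risk_difference", z_a, z_b, pa - pb,
                       x_setting=list(np.atleast_1d(x)))
        )
    return pd.DataFrame(rows)


LogitConversion = namedtuple("LogitConversion", ["beta_logit", "odds_ratio"])


def probit_to_logit(beta_probit: float) -> LogitConversion:
    """Convert a probit coefficient to the logit scale via the approximation
    logit(mu) ~= 1.6 * Phi^{-1}(mu), i.e. beta_logit ~= 1.6 * beta_probit.

    The approximation is accurate provided the event probability given the
    included predictors is not too close to 0 or 1.
    """
    beta_probit = np.asarray(beta_probit, dtype=float)
    if not np.all(np.isfinite(beta_probit)):
        raise ValueError("beta_probit must be finite")
    b = 1.6 * beta_probit
    return LogitConversion(beta_logit=b, odds_ratio=np.exp(b))


def saturated_model_parameter_count(M: int, DF: int) -> int:
    """Parameter count of a fully saturated basis-expansion model.

    Expanding each of M exposures in a basis with DF degrees of freedom and
    including every interaction among basis functions yields
    (1 + DF)^M - 1 regression parameters — the combinatorial blow-up that
    motivates kernel regularization of the exposure-response surface.
    """
    if int(M) != M or int(DF) != DF or M < 1 or DF < 1:
        raise ValueError("M and DF must be positive integers")
    return (1 + int(DF)) ** int(M) - 1
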