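"""Hybrid Gibbs / Metropolis-Hastings sampler for the marginalized posterior.

The subject-specific surface values h_i are integrated out analytically, so
the sampler moves only on (beta, sigma^2, lam, r/delta, lam_b, y*):

* beta — conjugate Gibbs draw from the GLS conditional under a flat prior;
* sigma^2 — conjugate inverse-gamma draw (gaussian family only; the probit
  family fixes sigma^2 = 1 for identifiability);
* lam — random-walk Metropolis-Hastings on log(lam) with a gamma prior;
* (r, delta) — spike-and-slab moves: one full random-order sweep over
  components (or selection groups) per iteration, each move a birth, death,
  within-slab random walk on log(r_m), or (hierarchical mode) a member swap;
* lam_b — random-walk MH on the log variance ratio of the cluster random
  intercept, which enters the marginal covariance as lam_b * GG';
* y* — probit data augmentation: draw h from its Gaussian full conditional,
  then each latent y*_i from a normal truncated to the side implied by y_i,
  and discard h again (partially collapsed Gibbs).

Per-iteration update order: (probit) latent draw, beta, sigma^2, lam,
r/delta, (clustered) intercept block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import linalg, stats

from .covariance import Workspace, gaussian_logpdf
from .data import MixtureDataset
from .params import GroupSpec, ParameterState, PriorSpec
from .samples import PosteriorSamples

__all__ = [
    "McmcControl",
    "marginal_loglik",
    "gibbs_update_beta",
    "gibbs_update_sigma2",
    "mh_update_lambda",
    "mh_update_r",
    "update_random_intercepts",
    "draw_random_intercepts",
    "sample_latent_response",
    "draw_h_given_resp",
    "run_mcmc",
]

logger = logging.getLogger(__name__)

_HALF_NORMAL_INIT = float(np.sqrt(2.0 / np.pi))  # E|N(0,1)|


@dataclass
class McmcControl:
    """Sampler settings (the ``control.params`` of the original interface)."""

    n_iter: int = 10000
    burn_frac: float = 0.5
    thin: int = 1
    seed: int | None = None
    varsel: bool = True
    # spike-and-slab sweeps per iteration: the (r, delta) block is the
    # slowest-mixing part of the chain, so it gets more proposals per
    # iteration than the scalar blocks
    n_r_sweeps: int = 3
    fix_lambda: bool = False  # freeze lam (oracle tests)
    fix_r: bool = False  # freeze (r, delta) (oracle tests)
    nugget: float = 1e-6
    verbose: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 2:
            raise ValueError("n_iter must be at least 2")
        if self.n_r_sweeps < 1:
            raise ValueError("n_r_sweeps must be at least 1")
        if self.thin < 1:
            raise ValueError("thin must be at least 1")
        if not 0 <= self.burn_frac < 1:
            raise ValueError("burn_frac must lie in [0, 1)")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def marginal_loglik(
    state: ParameterState,
    ws: Workspace,
    resp: np.ndarray | None = None,
    cov=None,
) -> float:
    """Marginal Gaussian log-likelihood log N(resp | X beta, sigma^2 C).

    ``resp`` defaults to the observed outcome, or the current latent y* for
    probit states. C = I + lam*K_r (+ lam_b*GG'); in predictive-process mode
    all solves are of knot dimension.
    """
    if resp is None:
        resp = state.y_star if state.y_star is not None else ws.y
    if cov is None:
        cov = ws.cov(state.lam, state.r, state.lam_b)
    value = ws.loglik(cov, resp, state.beta, state.sigma2)
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite marginal log-likelihood ({value}) at state {state!r}"
        )
    return value


# ---------------------------------------------------------------------------
# Gibbs blocks
# ---------------------------------------------------------------------------

def gibbs_update_beta(
    state: ParameterState,
    ws: Workspace,
    cov,
    resp: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw beta from N((X'C^{-1}X)^{-1} X'C^{-1} resp, sigma^2 (X'C^{-1}X)^{-1})."""
    X = ws.X
    P = X.shape[1]
    if P == 0:
        return state.beta
    W = cov.solve(X)
    prec = X.T @ W
    rhs = W.T @ resp
    if np.linalg.matrix_rank(prec, tol=None) < P or np.linalg.cond(prec) > 1e12:
        rank = np.linalg.matrix_rank(X)
        raise linalg.LinAlgError(
            f"X'C^{{-1}}X is singular (rank {rank} of {P} covariate columns "
            "appear collinear)"
        )
    L = linalg.cholesky(prec, lower=True)
    mean = linalg.cho_solve((L, True), rhs)
    noise = linalg.solve_triangular(L.T, rng.standard_normal(P), lower=False)
    return mean + np.sqrt(state.sigma2) * noise


def gibbs_update_sigma2(
    state: ParameterState,
    ws: Workspace,
    cov,
    resp: np.ndarray,
    priors: PriorSpec,
    rng: np.random.Generator,
) -> float:
    """Conjugate inverse-gamma draw; no-op (returns 1) for the probit family."""
    if ws.data.family == "binomial-probit":
        return 1.0
    resid = resp - ws.X @ state.beta if ws.X.shape[1] else resp
    shape = priors.sigma2_shape + 0.5 * ws.n
    rate = priors.sigma2_rate + 0.5 * cov.quad(resid)
    return float(rate / rng.gamma(shape, 1.0))


# ---------------------------------------------------------------------------
# Metropolis-Hastings blocks
# ---------------------------------------------------------------------------

def _lam_logprior(lam: float, shape: float, rate: float) -> float:
    if lam <= 0:
        return -np.inf
    return (shape - 1.0) * np.log(lam) - rate * lam


def mh_update_lambda(
    state: ParameterState,
    ws: Workspace,
    priors: PriorSpec,
    resp: np.ndarray,
    cov,
    ll: float,
    rng: np.random.Generator,
    sd: float | None = None,
) -> tuple[float, object, float, bool]:
    """Random-walk MH on log(lam); returns (lam, cov, loglik, accepted)."""
    sd = priors.sd_log_lambda if sd is None else sd
    if sd <= 0:
        raise ValueError("proposal sd must be positive")
    lam_p = state.lam * np.exp(sd * rng.standard_normal())
    cov_p = ws.cov(lam_p, state.r, state.lam_b)
    ll_p = ws.loglik(cov_p, resp, state.beta, state.sigma2)
    logratio = (
        ll_p
        - ll
        + _lam_logprior(lam_p, priors.lam_shape, priors.lam_rate)
        - _lam_logprior(state.lam, priors.lam_shape, priors.lam_rate)
        + np.log(lam_p)
        - np.log(state.lam)  # Jacobian of the log-scale walk
    )
    if np.log(rng.random()) < logratio:
        return lam_p, cov_p, ll_p, True
    return state.lam, cov, ll, False


def _make_loglik_fn(state, ws, resp, cov):
    """Default likelihood-of-r evaluator; returns (loglik, cov).

    In dense mode single-component proposals update the kernel matrix
    multiplicatively, K' = K * exp(-(r'_m - r_m) D_m), instead of rebuilding
    it from all M distance stacks.
    """
    current = {"cov": cov, "r": state.r.copy()}

    def fn(r_vec, m=None):
        base = current["cov"]
        dr = None if m is None else r_vec[m] - current["r"][m]
        if (
            dr is not None
            and base is not None
            and base.kind == "dense"
            and ws.knots is None
            # guard the multiplicative update against exp overflow when a
            # death removes a very large weight
            and abs(dr) * float(ws.D[m].max()) < 40.0
        ):
            K_p = base.K * np.exp(-dr * ws.D[m])
            cov_p = ws.cov_from_kernel(K_p, state.lam, state.lam_b)
        else:
            cov_p = ws.cov(state.lam, r_vec, state.lam_b)
        return ws.loglik(cov_p, resp, state.beta, state.sigma2), cov_p

    def advance(cov_new, r_new):
        current["cov"] = cov_new
        current["r"] = r_new.copy()

    fn.advance = advance
    return fn


def mh_update_r(
    state: ParameterState,
    ws: Workspace,
    priors: PriorSpec,
    groups: GroupSpec | None,
    resp: np.ndarray,
    cov,
    ll: float,
    rng: np.random.Generator,
    varsel: bool = True,
    loglik_fn=None,
    acc: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, object, float]:
    """One full sweep of spike-and-slab moves over components and groups.

    Component-wise mode: for each ungrouped exposure (random order), propose
    a birth (r_m drawn from the slab prior, which cancels against the prior
    in the MH ratio), a death (r_m -> 0), or a log-scale random walk within
    the slab. Hierarchical mode: per group, toggle the group on/off, swap
    the single active member, or walk its r; the one-active-member
    constraint is preserved by construction. With ``varsel=False`` all
    deltas stay 1 and only slab walks are proposed.

    Birth moves draw the proposed r_m from a lognormal proposal
    concentrated on the useful weight range (see :class:`PriorSpec`); the MH
    ratio carries the slab(r') / proposal(r') correction, so the
    spike-and-slab prior itself is untouched.

    ``loglik_fn(r_vec, m=None) -> (loglik, cov)`` may be injected (tests use
    a constant likelihood to check prior recovery).
    """
    if loglik_fn is None:
        loglik_fn = _make_loglik_fn(state, ws, resp, cov)
    if acc is None:
        acc = {}

    r = state.r.copy()
    delta = state.delta.copy()
    groups = groups or GroupSpec()
    M = r.shape[0]
    logit_pi = float(np.log(priors.pi) - np.log1p(-priors.pi))

    def attempt(kind, r_prop, extra_logratio, m=None):
        nonlocal r, delta, cov, ll
        try:
            ll_p, cov_p = loglik_fn(r_prop, m)
        except TypeError:
            ll_p, cov_p = loglik_fn(r_prop)
        a = acc.setdefault(kind, [0, 0])
        a[1] += 1
        if np.log(rng.random()) < ll_p - ll + extra_logratio:
            a[0] += 1
            r = r_prop
            cov = cov_p
            ll = ll_p
            if hasattr(loglik_fn, "advance"):
                loglik_fn.advance(cov_p, r_prop)
            return True
        return False

    def walk(m):
        r_new = r[m] * np.exp(priors.sd_log_r * rng.standard_normal())
        lp_new = priors.slab_logpdf(r_new)
        if not np.isfinite(lp_new):
            a = acc.setdefault("walk", [0, 0])
            a[1] += 1
            return
        extra = (
            lp_new - priors.slab_logpdf(r[m]) + np.log(r_new) - np.log(r[m])
        )
        r_prop = r.copy()
        r_prop[m] = r_new
        attempt("walk", r_prop, extra, m)

    def birth_extra(r_new, q_death):
        # prior ratio pi*slab/(1-pi) times proposal ratio q_death/g(r_new)
        return (
            logit_pi + priors.slab_logpdf(r_new) - priors.birth_logpdf(r_new)
            + np.log(q_death)
        )

    def death_extra(r_old, q_death):
        return (
            -logit_pi - priors.slab_logpdf(r_old) + priors.birth_logpdf(r_old)
            - np.log(q_death)
        )

    # ---- ungrouped components -------------------------------------------
    ungrouped = np.array(groups.ungrouped(M), dtype=int)
    for m in rng.permutation(ungrouped) if ungrouped.size else []:
        if not varsel:
            walk(m)
            continue
        if delta[m] == 0:
            # birth proposed with probability 1; reverse (death) with 1/2
            r_prop = r.copy()
            r_prop[m] = priors.birth_rvs(rng)
            if attempt("birth", r_prop, birth_extra(r_prop[m], 0.5), m):
                delta[m] = 1
        elif rng.random() < 0.5:
            r_prop = r.copy()
            r_prop[m] = 0.0
            if attempt("death", r_prop, death_extra(r[m], 0.5), m):
                delta[m] = 0
        else:
            walk(m)

    # one global swap proposal per sweep: transfer the weight of a random
    # active component to a random inactive one (symmetric, prior-neutral).
    # Correlated exposures compete for inclusion, and birth/death chains
    # resolve that contention very slowly; a direct exchange move does not.
    if varsel and ungrouped.size:
        on = ungrouped[delta[ungrouped] == 1]
        off = ungrouped[delta[ungrouped] == 0]
        if on.size and off.size:
            m_on = on[rng.integers(on.size)]
            m_off = off[rng.integers(off.size)]
            r_prop = r.copy()
            r_prop[m_off] = r_prop[m_on]
            r_prop[m_on] = 0.0
            if attempt("swap", r_prop, 0.0):
                delta[m_on] = 0
                delta[m_off] = 1

    # ---- hierarchical groups --------------------------------------------
    if varsel and groups.groups:
        labels = list(groups.groups)
        for gi in rng.permutation(len(labels)):
            members = groups.groups[labels[gi]]
            g = len(members)
            # death proposal probability: 1/2, plus the swap branch (1/4)
            # collapsing to a toggle for singleton groups
            q_death = 0.5 + (0.25 if g == 1 else 0.0)
            active = [m for m in members if delta[m] == 1]
            if not active:
                m = members[rng.integers(g)]
                r_prop = r.copy()
                r_prop[m] = priors.birth_rvs(rng)
                if attempt("birth", r_prop, birth_extra(r_prop[m], q_death), m):
                    delta[m] = 1
                continue
            m = active[0]
            u = rng.random()
            if u < q_death:
                r_prop = r.copy()
                r_prop[m] = 0.0
                if attempt("death", r_prop, death_extra(r[m], q_death), m):
                    delta[m] = 0
            elif u < 0.75:
                others = [mm for mm in members if mm != m]
                m_new = others[rng.integers(len(others))]
                r_prop = r.copy()
                r_prop[m_new] = r_prop[m]
                r_prop[m] = 0.0
                if attempt("swap", r_prop, 0.0):
                    delta[m] = 0
                    delta[m_new] = 1
            else:
                walk(m)

    return r, delta, cov, ll


def update_random_intercepts(
    state: ParameterState,
    ws: Workspace,
    priors: PriorSpec,
    resp: np.ndarray,
    cov,
    ll: float,
    rng: np.random.Generator,
    sd: float | None = None,
) -> tuple[float, object, float, bool]:
    """Random-walk MH on log(lam_b), the marginalized random-intercept
    variance ratio tau_b^2 / sigma^2. Returns (lam_b, cov, loglik, accepted)."""
    if not ws.clustered:
        raise ValueError("dataset has no cluster labels")
    sd = priors.sd_log_taub if sd is None else sd
    lam_b_p = state.lam_b * np.exp(sd * rng.standard_normal())
    cov_p = ws.cov(state.lam, state.r, lam_b_p)
    ll_p = ws.loglik(cov_p, resp, state.beta, state.sigma2)
    logratio = (
        ll_p
        - ll
        + _lam_logprior(lam_b_p, priors.lam_b_shape, priors.lam_b_rate)
        - _lam_logprior(state.lam_b, priors.lam_b_shape, priors.lam_b_rate)
        + np.log(lam_b_p)
        - np.log(state.lam_b)
    )
    if np.log(rng.random()) < logratio:
        return lam_b_p, cov_p, ll_p, True
    return state.lam_b, cov, ll, False


def draw_random_intercepts(
    state: ParameterState,
    ws: Workspace,
    cov,
    resp: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """On-demand conjugate draw of the cluster intercepts b given a state.

    b | resp ~ N(lam_b G'C^{-1} resid, sigma^2 (lam_b I - lam_b^2 G'C^{-1}G)).
    """
    if not ws.clustered:
        raise ValueError("dataset has no cluster labels")
    resid = resp - ws.X @ state.beta if ws.X.shape[1] else resp
    lam_b = state.lam_b
    GtCi = cov.solve(ws.G).T  # (C, n)
    mean = lam_b * (GtCi @ resid)
    covb = state.sigma2 * (lam_b * np.eye(ws.G.shape[1]) - lam_b**2 * (GtCi @ ws.G))
    return _draw_mvn(rng, mean, covb)


# ---------------------------------------------------------------------------
# probit data augmentation
# ---------------------------------------------------------------------------

def sample_latent_response(
    mean: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw latent y*_i ~ N(mean_i, 1) truncated to (0, inf) where y_i = 1
    and to (-inf, 0] where y_i = 0."""
    mean = np.asarray(mean, float)
    if not np.all(np.isfinite(mean)):
        raise FloatingPointError("non-finite latent conditional mean")
    y = np.asarray(y)
    a = np.where(y == 1, -mean, -np.inf)
    b = np.where(y == 1, np.inf, -mean)
    return stats.truncnorm.rvs(a, b, loc=mean, scale=1.0, random_state=rng)


def _draw_mvn(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate normal draw robust to a PSD (rank-deficient) covariance."""
    cov = 0.5 * (cov + cov.T)
    if not cov.any():
        return mean.copy()
    scale = max(np.max(np.diag(cov)), 1.0)
    for jit in (0.0, 1e-12, 1e-9):
        try:
            L = linalg.cholesky(cov + jit * scale * np.eye(cov.shape[0]), lower=True)
            return mean + L @ rng.standard_normal(mean.shape[0])
        except linalg.LinAlgError:
            continue
    w, V = linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return mean + (V * np.sqrt(w)) @ rng.standard_normal(mean.shape[0])


def draw_h_given_resp(
    state: ParameterState,
    ws: Workspace,
    cov,
    resp: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the surface vector h at the training points from its Gaussian
    full conditional given the (latent) response and current parameters."""
    resid = resp - ws.X @ state.beta if ws.X.shape[1] else resp
    lam, s2 = state.lam, state.sigma2
    if lam == 0:
        return np.zeros(ws.n)
    if cov.kind == "dense":
        K = cov.K
        Ci_resid = cov.solve(resid)
        mean = lam * (K @ Ci_resid)
        covh = s2 * (lam * K - lam**2 * (K @ cov.solve(K)))
        return _draw_mvn(rng, mean, covh)
    A = cov.lrk.A  # (n, k)
    Ci_resid = cov.solve(resid)
    mean = lam * (A @ (A.T @ Ci_resid))
    CiA = cov.solve(A)
    S = s2 * (lam * np.eye(A.shape[1]) - lam**2 * (A.T @ CiA))
    w = _draw_mvn(rng, np.zeros(A.shape[1]), S)
    return mean + A @ w


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _initial_state(data: MixtureDataset, ws: Workspace, groups: GroupSpec | None,
                   control: McmcControl) -> tuple[ParameterState, np.ndarray]:
    probit = data.family == "binomial-probit"
    resp = (2.0 * data.y - 1.0) * _HALF_NORMAL_INIT if probit else data.y.copy()
    if data.P:
        beta, *_ = np.linalg.lstsq(data.X, resp, rcond=None)
        resid = resp - data.X @ beta
    else:
        beta = np.zeros(0)
        resid = resp
    sigma2 = 1.0 if probit else max(float(np.var(resid)), 1e-8)
    delta = np.ones(data.M, dtype=int)
    if control.varsel and groups is not None:
        for members in groups.groups.values():
            for m in members[1:]:
                delta[m] = 0
    r = 0.1 * delta.astype(float)
    state = ParameterState(
        beta=beta,
        sigma2=sigma2,
        lam=1.0,
        r=r,
        delta=delta,
        lam_b=0.1 if ws.clustered else None,
        y_star=resp.copy() if probit else None,
    )
    return state, resp


def run_mcmc(
    data: MixtureDataset,
    priors: PriorSpec | None = None,
    groups: GroupSpec | None = None,
    control: McmcControl | None = None,
    knots: np.ndarray | None = None,
    centers: np.ndarray | None = None,
    scales: np.ndarray | None = None,
) -> PosteriorSamples:
    """Fit the kernel machine model by MCMC and return the stored states.

    ``data.Z`` is used as given (standardize beforehand; pass the
    ``centers``/``scales`` so that downstream summaries can place quantile
    grids on the original exposure scale). Identical seeds yield
    bit-identical sample paths.
    """
    priors = priors or PriorSpec()
    control = control or McmcControl()
    if control.seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    else:
        seed = int(control.seed)
    rng = np.random.default_rng(seed)
    ws = Workspace(data, knots=knots, nugget=control.nugget)
    probit = data.family == "binomial-probit"

    state, resp = _initial_state(data, ws, groups, control)
    cov = ws.cov(state.lam, state.r, state.lam_b)
    ll = ws.loglik(cov, resp, state.beta, state.sigma2)

    burn = int(round(control.n_iter * control.burn_frac))
    keep_beta, keep_s2, keep_lam = [], [], []
    keep_r, keep_delta, keep_tau, keep_ystar = [], [], [], []
    acc_lambda = [0, 0]
    acc_tau = [0, 0]
    acc_r: dict[str, list[int]] = {}

    for it in range(control.n_iter):
        try:
            if probit:
                h = draw_h_given_resp(state, ws, cov, state.y_star, rng)
                lin = h + (ws.X @ state.beta if data.P else 0.0)
                state.y_star = sample_latent_response(lin, data.y, rng)
                resp = state.y_star
                ll = ws.loglik(cov, resp, state.beta, state.sigma2)
            if data.P:
                state.beta = gibbs_update_beta(state, ws, cov, resp, rng)
            if not probit:
                state.sigma2 = gibbs_update_sigma2(state, ws, cov, resp, priors, rng)
            ll = ws.loglik(cov, resp, state.beta, state.sigma2)
            if not control.fix_lambda:
                acc_lambda[1] += 1
                state.lam, cov, ll, a = mh_update_lambda(
                    state, ws, priors, resp, cov, ll, rng
                )
                acc_lambda[0] += int(a)
            if not control.fix_r:
                for _ in range(control.n_r_sweeps):
                    state.r, state.delta, cov, ll = mh_update_r(
                        state, ws, priors, groups, resp, cov, ll, rng,
                        varsel=control.varsel, acc=acc_r,
                    )
            if ws.clustered:
                acc_tau[1] += 1
                state.lam_b, cov, ll, a = update_random_intercepts(
                    state, ws, priors, resp, cov, ll, rng
                )
                acc_tau[0] += int(a)
        except Exception as err:
            raise RuntimeError(
                f"MCMC aborted at iteration {it}: {err} (state snapshot: {state!r})"
            ) from err

        if it >= burn and (it - burn) % control.thin == 0:
            keep_beta.append(state.beta.copy())
            keep_s2.append(state.sigma2)
            keep_lam.append(state.lam)
            keep_r.append(state.r.copy())
            keep_delta.append(state.delta.copy())
            if ws.clustered:
                keep_tau.append(state.lam_b * state.sigma2)
            if probit:
                keep_ystar.append(state.y_star.copy())
        if control.verbose and (it + 1) % max(1, control.n_iter // 10) == 0:
            logger.info(
                "iter %d/%d loglik %.2f acc(lambda)=%.2f",
                it + 1, control.n_iter, ll,
                acc_lambda[0] / max(acc_lambda[1], 1),
            )

    def _rate(c):
        return c[0] / c[1] if c[1] else None

    acceptance = {
        "lambda": _rate(acc_lambda),
        "tau_b2": _rate(acc_tau) if ws.clustered else None,
        "r": {k: _rate(v) for k, v in acc_r.items()},
    }
    M = data.M
    samples = PosteriorSamples(
        beta=np.array(keep_beta).reshape(len(keep_beta), data.P),
        sigma2=np.array(keep_s2),
        lam=np.array(keep_lam),
        r=np.array(keep_r).reshape(len(keep_r), M),
        delta=np.array(keep_delta, dtype=int).reshape(len(keep_delta), M),
        data=data,
        centers=np.zeros(M) if centers is None else np.asarray(centers, float),
        scales=np.ones(M) if scales is None else np.asarray(scales, float),
        seed=seed,
        control=asdict(control) | {"seed": seed},
        acceptance=acceptance,
        varsel=bool(control.varsel),
        tau_b2=np.array(keep_tau) if ws.clustered else None,
        y_star=np.array(keep_ystar) if probit else None,
        knots=None if knots is None else np.asarray(knots, float),
        nugget=control.nugget,
        groups=groups,
    )
    samples._ws = ws
    return samples
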